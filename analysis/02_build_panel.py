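#!/usr/bin/env python
"""Aggregate the registry into pseudo-panel cells.

Builds the overall panel (all donations) and the voluntary panel (pre-ban
FRD donations removed) on the 24-cohort x 14-section crossing, dropping
cells with fewer than 30 distinct donors, and writes cells.csv /
cells_voluntary.csv.
"""

from pathlib import Path

from plateletpanel import GeneratorConfig, build_panel, read_registry

OUT = Path(__file__).resolve().parent.parent / "results" / "analysis"


def main() -> None:
    donors, donations = read_registry(OUT)
    scheme = GeneratorConfig().scheme
    for frd_filter, name in (("keep_all", "cells.csv"),
                             ("drop_frd_pre_ban", "cells_voluntary.csv")):
        panel = build_panel(donors, donations, scheme, 30, frd_filter)
        panel.to_csv(OUT / name)
        print(f"{panel.label}: {len(panel)} cells >= 30 donors "
              f"({panel.n_cohorts} cohorts) -> {OUT / name}")


if __name__ == "__main__":
    main()
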