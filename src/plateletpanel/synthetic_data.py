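"""Synthetic plateletpheresis donation data with known ground truth.

Two generator levels are deliberate:

* :func:`generate_cell_panel` draws cell means directly from the two-piecewise
  random-intercept model (``mean = X beta_true + u_cohort + eps``), isolating
  the mixed-model machinery from aggregation effects;
* :func:`generate_registry` simulates individual donors and donation events —
  entry, retention, family/replacement (FRD) propensity, per-donation units,
  and the 24-collections-per-rolling-year regulatory cap — so the whole
  pipeline (section binning, history classification, cohort grouping,
  cell filtering, model fit, FRD sensitivity) can be exercised end to end.

One root seed drives everything; each donor gets a child random stream spawned
deterministically from (seed, donor index), so enlarging the registry never
perturbs already-generated donors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, timedelta

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError
from .pseudo_panel import (BIRTH_BANDS, HISTORY_LEVELS, CrossSectionScheme,
                           PanelDataset, all_cohort_keys)

#: fixed-effect term keys understood by the cell-mean surface
BETA_TERMS = (
    "intercept", "time_before", "time_after",
    "gender[male]",
    "history[WB]", "history[PLT]", "history[Both]",
    "time_after:gender[male]",
    "time_after:history[WB]", "time_after:history[PLT]", "time_after:history[Both]",
)

#: reference coefficient set in the Guangzhou-centre magnitude range (units U)
GZ_BETAS = {
    "intercept": 0.8636,
    "time_before": 0.0111,
    "time_after": 0.0404,
    "gender[male]": 1.3370,
    "history[WB]": 0.1790,
    "history[PLT]": 2.6243,
    "history[Both]": 3.9440,
    "time_after:gender[male]": 0.0550,
    "time_after:history[WB]": 0.0331,
    "time_after:history[PLT]": 0.0698,
    "time_after:history[Both]": 0.0444,
}

#: reference coefficient set in the Chengdu-centre magnitude range (units U)
CD_BETAS = {
    "intercept": 0.9637,
    "time_before": 0.0077,
    "time_after": 0.0441,
    "gender[male]": 0.7449,
    "history[WB]": 0.1928,
    "history[PLT]": 2.1231,
    "history[Both]": 3.2293,
    "time_after:gender[male]": 0.0325,
    "time_after:history[WB]": 0.0069,
    "time_after:history[PLT]": 0.1373,
    "time_after:history[Both]": 0.0507,
}

# FRD share of donors per cross-section: climbing through the pre-ban decade,
# collapsing in the announcement half-year, zero once the ban is effective.
DEFAULT_FRD_FRACTIONS = (0.154, 0.241, 0.242, 0.289, 0.342, 0.361, 0.347,
                         0.400, 0.392, 0.419, 0.185, 0.0, 0.0, 0.0)


def _betas_with_birth_bands(betas: dict) -> dict:
    out = dict(betas)
    out.setdefault("birth_band[1975-1984]", 0.0)
    out.setdefault("birth_band[1985-2001]", 0.0)
    return out


@dataclass
class GeneratorConfig:
    """Study conditions for both generator levels.

    Probability vectors must sum to 1; ``frd_fraction_by_section`` entries
    for post-ban sections are forced to zero at validation.
    """

    n_donors: int = 20000
    window_start: date = date(2012, 10, 1)
    n_sections: int = 14
    section_months: int = 6
    ban_breakpoint: int = 11
    p_male: float = 0.73
    birth_band_probs: tuple = (0.20, 0.33, 0.47)
    history_mix: tuple = (0.52, 0.15, 0.20, 0.13)  # None, WB, PLT, Both at entry
    frd_fraction_by_section: tuple = DEFAULT_FRD_FRACTIONS
    true_betas: dict = field(default_factory=lambda: dict(GZ_BETAS))
    sigma_u: float = 0.3
    sigma_e: float = 0.3
    max_donations_per_year: int = 24
    seed: int = 0

    # cell-level generator
    mean_donors_per_cell: float = 300.0

    # registry-level mechanics (free parameters of the event model)
    retention_prob: float = 0.55          # stay active next section
    frd_retention_prob: float = 0.30      # FRD donors churn faster
    donation_rate_base: float = 0.45      # voluntary extra-donation Poisson rate ...
    donation_rate_slope_pre: float = 0.035    # ... rising before the ban
    donation_rate_slope_post: float = 0.25    # ... and faster after it
    male_rate_boost: float = 0.15         # men donate somewhat more often
    plt_history_rate_boost: float = 0.30  # platelet-experienced donors return more
    wb_history_rate_boost: float = 0.05
    frd_entry_boost: float = 1.5          # extra pre-ban entrants recruited via FRD
    units_probs: tuple = (0.25, 0.45, 0.30)       # voluntary P(units = 1, 1.5, 2)
    frd_units_probs: tuple = (0.70, 0.25, 0.05)   # FRD donations skew low
    frd_single_donation: bool = True      # FRD donors give once per section

    UNIT_CHOICES = (1.0, 1.5, 2.0)

    @property
    def scheme(self) -> CrossSectionScheme:
        return CrossSectionScheme(self.window_start, self.n_sections,
                                  self.section_months, self.ban_breakpoint)

    def validate(self) -> "GeneratorConfig":
        if self.n_donors < 1:
            raise ValueError("n_donors must be >= 1")
        for name in ("birth_band_probs", "history_mix", "units_probs", "frd_units_probs"):
            v = np.asarray(getattr(self, name), dtype=float)
            if v.min() < 0 or abs(v.sum() - 1.0) > 1e-12:
                raise ConfigError(f"{name} must be a probability vector summing to 1")
        if not 0.0 <= self.p_male <= 1.0:
            raise ConfigError("p_male must be a probability")
        frd = list(self.frd_fraction_by_section)
        if len(frd) != self.n_sections:
            raise ConfigError("frd_fraction_by_section must have one entry per section")
        if any(not 0.0 <= f <= 1.0 for f in frd):
            raise ConfigError("frd fractions must be probabilities")
        for s in range(self.ban_breakpoint, self.n_sections):
            frd[s] = 0.0  # ban: no FRD after the breakpoint
        object.__setattr__(self, "frd_fraction_by_section", tuple(frd))
        if self.sigma_u < 0 or self.sigma_e <= 0:
            raise ConfigError("need sigma_u >= 0 and sigma_e > 0")
        missing = [t for t in BETA_TERMS if t not in self.true_betas]
        if missing:
            raise ConfigError(f"true_betas missing coefficient(s): {missing}")
        return self

    # ---- config file round trip -------------------------------------------------
    def to_dict(self) -> dict:
        d = {k: v for k, v in self.__dict__.items()}
        d["window_start"] = self.window_start.isoformat()
        for k in ("birth_band_probs", "history_mix", "frd_fraction_by_section",
                  "units_probs", "frd_units_probs"):
            d[k] = list(d[k])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        d = dict(d)
        unknown = set(d) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"unknown config fields: {sorted(unknown)}")
        if "window_start" in d and isinstance(d["window_start"], str):
            d["window_start"] = date.fromisoformat(d["window_start"])
        for k in ("birth_band_probs", "history_mix", "frd_fraction_by_section",
                  "units_probs", "frd_units_probs"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d).validate()

    @classmethod
    def from_file(cls, path) -> "GeneratorConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def cell_mean_surface(config: GeneratorConfig) -> pd.DataFrame:
    """Noiseless cell means implied by ``true_betas`` for every cohort/section."""
    config.validate()
    betas = _betas_with_birth_bands(config.true_betas)
    k = config.ban_breakpoint
    rows = []
    for cohort in all_cohort_keys():
        for s in range(1, config.n_sections + 1):
            tb, ta = min(s, k), max(s - k, 0)
            mu = betas["intercept"] + betas["time_before"] * tb + betas["time_after"] * ta
            if cohort.gender == "male":
                mu += betas["gender[male]"] + betas["time_after:gender[male]"] * ta
            if cohort.history != "None":
                mu += betas[f"history[{cohort.history}]"]
                mu += betas[f"time_after:history[{cohort.history}]"] * ta
            if cohort.birth_band != BIRTH_BANDS[0]:
                mu += betas[f"birth_band[{cohort.birth_band}]"]
            rows.append((s, cohort.gender, cohort.birth_band, cohort.history, mu))
    return pd.DataFrame(rows, columns=["section", "gender", "birth_band", "history", "mu"])


def generate_cell_panel(config: GeneratorConfig) -> PanelDataset:
    """Draw a full cell panel from the two-piecewise random-intercept model.

    Returns all ``24 * n_sections`` cells (no size filter): each cell carries a
    simulated donor count and an outcome ``mu + u_cohort + eps`` with
    ``u_cohort ~ N(0, sigma_u^2)`` and ``eps ~ N(0, sigma_e^2)``.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    surf = cell_mean_surface(config)
    cohorts = all_cohort_keys()
    u = rng.normal(0.0, config.sigma_u, size=len(cohorts))
    u_map = {(c.gender, c.birth_band, c.history): u[i] for i, c in enumerate(cohorts)}
    eps = rng.normal(0.0, config.sigma_e, size=len(surf))
    n_donors = rng.poisson(config.mean_donors_per_cell, size=len(surf)) + 30

    df = surf.copy()
    df["n_donors"] = n_donors
    df["outcome"] = (df["mu"].to_numpy()
                     + np.array([u_map[(g, b, h)] for g, b, h in
                                 zip(df["gender"], df["birth_band"], df["history"])])
                     + eps)
    df["total_units"] = df["outcome"] * df["n_donors"]
    df = df.drop(columns="mu").sort_values(
        ["section", "gender", "birth_band", "history"], ignore_index=True)
    cols = ["section", "gender", "birth_band", "history", "n_donors", "total_units", "outcome"]
    return PanelDataset(df[cols], config.scheme, min_cell_size=0, label="synthetic-cells")


# ---------------------------------------------------------------------------
# registry-level generator
# ---------------------------------------------------------------------------

def _donor_rng(seed: int, donor_index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(donor_index,)))


def _feasible_birth_years(band: str, entry_year: int) -> np.ndarray:
    lo, hi = {b: (int(b[:4]), int(b[-4:])) for b in BIRTH_BANDS}[band]
    lo = max(lo, entry_year - 60)   # age <= 60 at entry
    hi = min(hi, entry_year - 18)   # age >= 18 at entry
    return np.arange(lo, hi + 1)


def generate_registry(config: GeneratorConfig):
    """Simulate donor profiles and donation events.

    Returns ``(donors, donations)`` DataFrames with the ``donors.csv`` /
    ``donations.csv`` schemas.  Mechanics per donor: uniform entry section;
    geometric retention across subsequent sections; a persistent latent
    uniform draw makes the donor an FRD donor in section ``s`` exactly when
    it falls below ``frd_fraction_by_section[s]`` (so section margins match
    the configured fractions while FRD status is donor-sticky); voluntary
    donor-sections contribute ``1 + Poisson(rate_s)`` donations with the rate
    rising before and faster after the ban and boosted for male and
    donation-experienced donors, FRD donor-sections a single donation with a
    low-units distribution; FRD donor-sections carry a lower retention
    probability (family/replacement donors rarely return), which yields the
    fewer-donors-more-blood pattern once the ban removes them; a rolling
    365-day cap of ``max_donations_per_year`` collections is enforced
    record-wise.
    """
    config.validate()
    scheme = config.scheme
    bounds = scheme.boundaries
    k = config.ban_breakpoint

    donors, donations = [], []
    hist_flags = {"None": (False, False), "WB": (True, False),
                  "PLT": (False, True), "Both": (True, True)}
    # entry is heavier in pre-ban sections: family/replacement recruitment
    # brings in extra first-time donors that the ban later removes
    entry_w = np.array([1.0 + config.frd_entry_boost * f
                        for f in config.frd_fraction_by_section])
    entry_p = entry_w / entry_w.sum()
    for i in range(config.n_donors):
        rng = _donor_rng(config.seed, i)
        entry = int(rng.choice(config.n_sections, p=entry_p)) + 1
        gender = "male" if rng.random() < config.p_male else "female"
        band = BIRTH_BANDS[rng.choice(3, p=np.asarray(config.birth_band_probs, float))]
        birth_year = int(rng.choice(_feasible_birth_years(band, bounds[entry - 1].year)))
        pre_wb, pre_plt = hist_flags[HISTORY_LEVELS[
            rng.choice(4, p=np.asarray(config.history_mix, float))]]
        frd_latent = rng.random()
        donor_id = f"D{i:07d}"
        donors.append((donor_id, gender, birth_year, pre_wb, pre_plt))

        boost = (config.male_rate_boost * (gender == "male")
                 + config.plt_history_rate_boost * pre_plt
                 + config.wb_history_rate_boost * pre_wb)
        recs = []
        s = entry
        while s <= config.n_sections:
            is_frd = s <= k and frd_latent < config.frd_fraction_by_section[s - 1]
            if is_frd and config.frd_single_donation:
                n_d = 1
            else:
                rate = (config.donation_rate_base
                        + config.donation_rate_slope_pre * min(s, k)
                        + config.donation_rate_slope_post * max(s - k, 0)
                        + boost)
                n_d = 1 + int(rng.poisson(rate))
            span = (bounds[s] - bounds[s - 1]).days
            offsets = np.sort(rng.integers(0, span, size=n_d))
            probs = config.frd_units_probs if is_frd else config.units_probs
            units = rng.choice(GeneratorConfig.UNIT_CHOICES, size=n_d,
                               p=np.asarray(probs, float))
            for off, un in zip(offsets, units):
                recs.append((bounds[s - 1] + timedelta(days=int(off)), float(un), is_frd))
            stay = config.frd_retention_prob if is_frd else config.retention_prob
            if rng.random() >= stay:
                break
            s += 1

        # regulatory cap: at most max_donations_per_year in any rolling 365 days
        kept_dates = []
        for d, un, flag in recs:
            cutoff = d - timedelta(days=364)
            recent = sum(1 for kd in kept_dates if kd >= cutoff)
            if recent < config.max_donations_per_year:
                kept_dates.append(d)
                donations.append((donor_id, d.isoformat(), un, flag))

    donors_df = pd.DataFrame(donors, columns=["donor_id", "gender", "birth_year",
                                              "pre_window_wb", "pre_window_plt"])
    donations_df = pd.DataFrame(donations, columns=["donor_id", "date", "units", "is_frd"])
    return donors_df, donations_df


def write_registry(donors: pd.DataFrame, donations: pd.DataFrame, outdir) -> None:
    from pathlib import Path
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    donors.to_csv(outdir / "donors.csv", index=False)
    donations.to_csv(outdir / "donations.csv", index=False)


def read_registry(indir):
    from pathlib import Path
    from .errors import SchemaError
    from .pseudo_panel import DONATION_COLUMNS, DONOR_COLUMNS
    indir = Path(indir)
    donors = pd.read_csv(indir / "donors.csv")
    donations = pd.read_csv(indir / "donations.csv")
    for df, cols, name in ((donors, DONOR_COLUMNS, "donors.csv"),
                           (donations, DONATION_COLUMNS, "donations.csv")):
        missing = [c for c in cols if c not in df.columns]
        if missing:
            raise SchemaError(f"{name} missing columns: {missing}", missing)
    return donors, donations
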