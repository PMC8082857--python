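"""Pseudo-panel construction from individual plateletpheresis donation records.

A pseudo panel turns repeated cross-sectional data into cohort-level
longitudinal data: donors observed in each half-yearly cross-section are
grouped on time-invariant covariates (gender, birth-year band, blood-donation
history), and the outcome of each (cross-section, cohort) cell is the mean
number of apheresis platelet units per distinct donor.  Panel-style mixed
models can then be fitted to the cells without tracking individuals.

The default scheme covers fourteen six-month cross-sections from 2012-10-01,
with the family/replacement-donation (FRD) ban opening the 12th section
(2018-04-01), i.e. a breakpoint after section 11.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date

import numpy as np
import pandas as pd

from .errors import JoinError, OutOfWindowError, SchemaError

GENDERS = ("female", "male")
BIRTH_BANDS = ("1952-1974", "1975-1984", "1985-2001")
HISTORY_LEVELS = ("None", "WB", "PLT", "Both")

#: column schema of the record-level inputs
DONOR_COLUMNS = ("donor_id", "gender", "birth_year", "pre_window_wb", "pre_window_plt")
DONATION_COLUMNS = ("donor_id", "date", "units", "is_frd")
CELL_COLUMNS = ("section", "gender", "birth_band", "history", "n_donors", "total_units", "outcome")


def _add_months(d: date, months: int) -> date:
    y, m = divmod(d.year * 12 + (d.month - 1) + months, 12)
    return date(y, m + 1, d.day)


@dataclass(frozen=True)
class CrossSectionScheme:
    """Partition of the observation window into half-open cross-sections.

    Section ``s`` (1-based) covers ``[start + (s-1)*section_months,
    start + s*section_months)``.  ``ban_breakpoint`` is the index of the last
    pre-ban section.
    """

    window_start: date = date(2012, 10, 1)
    n_sections: int = 14
    section_months: int = 6
    ban_breakpoint: int = 11

    def __post_init__(self):
        if self.n_sections < 2 or self.section_months < 1:
            raise ValueError("need n_sections >= 2 and section_months >= 1")
        if not (1 <= self.ban_breakpoint < self.n_sections):
            raise ValueError("ban_breakpoint must satisfy 1 <= k < n_sections")

    @property
    def boundaries(self) -> list[date]:
        """n_sections + 1 boundary dates; section s is [b[s-1], b[s])."""
        return [_add_months(self.window_start, i * self.section_months)
                for i in range(self.n_sections + 1)]

    @property
    def window_end(self) -> date:
        return self.boundaries[-1]

    def section_start(self, s: int) -> date:
        return self.boundaries[s - 1]

    def assign_section(self, d: date) -> int:
        b = self.boundaries
        if d < b[0] or d >= b[-1]:
            raise OutOfWindowError(
                f"date {d.isoformat()} outside observation window "
                f"[{b[0].isoformat()}, {b[-1].isoformat()})")
        # linear scan is fine for <= a few dozen sections
        for s in range(1, self.n_sections + 1):
            if d < b[s]:
                return s
        raise AssertionError("unreachable")

    def assign_sections(self, dates: pd.Series) -> np.ndarray:
        """Vectorised section assignment for a Series of datetime64/date."""
        bounds = pd.to_datetime(self.boundaries)
        vals = pd.to_datetime(dates)
        idx = np.searchsorted(bounds.values, vals.values, side="right")
        bad = (idx < 1) | (idx > self.n_sections)
        if bad.any():
            offending = vals[bad].dt.date.astype(str).tolist()[:5]
            raise OutOfWindowError(f"dates outside observation window: {offending}")
        return idx.astype(int)


def assign_section(d: date, scheme: CrossSectionScheme) -> int:
    """Cross-section index (1-based) containing calendar date ``d``."""
    return scheme.assign_section(d)


def birth_band(birth_year: int) -> str:
    """Map a birth year to its cohort band; boundaries inclusive."""
    if not 1952 <= birth_year <= 2001:
        raise ValueError(f"birth_year {birth_year} outside [1952, 2001]")
    if birth_year <= 1974:
        return BIRTH_BANDS[0]
    if birth_year <= 1984:
        return BIRTH_BANDS[1]
    return BIRTH_BANDS[2]


@dataclass(frozen=True)
class CohortKey:
    """One of the 24 cohorts: gender x birth band x donation history."""

    gender: str
    birth_band: str
    history: str

    def __post_init__(self):
        if self.gender not in GENDERS:
            raise ValueError(f"unknown gender {self.gender!r}")
        if self.birth_band not in BIRTH_BANDS:
            raise ValueError(f"unknown birth band {self.birth_band!r}")
        if self.history not in HISTORY_LEVELS:
            raise ValueError(f"unknown history level {self.history!r}")


def all_cohort_keys() -> list[CohortKey]:
    """All 2 x 3 x 4 = 24 cohort keys in canonical order."""
    return [CohortKey(g, b, h) for g in GENDERS for b in BIRTH_BANDS for h in HISTORY_LEVELS]


@dataclass(frozen=True)
class DonorProfile:
    donor_id: object
    gender: str
    birth_year: int
    pre_window_wb: bool = False
    pre_window_plt: bool = False


@dataclass(frozen=True)
class DonationRecord:
    donor_id: object
    date: date
    units: float
    is_frd: bool = False


@dataclass(frozen=True)
class PanelCell:
    section: int
    cohort: CohortKey
    n_donors: int
    total_units: float

    @property
    def outcome(self) -> float:
        """Mean apheresis platelet units per distinct donor (U)."""
        return self.total_units / self.n_donors


def classify_history(profile: DonorProfile,
                     prior_platelet_dates,
                     section_start: date) -> str:
    """Donation-history level of a donor at the start of a cross-section.

    ``prior_platelet_dates`` are the dates of the donor's in-window apheresis
    donations; only events strictly before ``section_start`` count, together
    with the pre-window flags.  Whole-blood history can only enter through
    the pre-window flag (in-window whole-blood donations are out of scope).
    """
    has_wb = bool(profile.pre_window_wb)
    has_plt = bool(profile.pre_window_plt) or any(
        d < section_start for d in prior_platelet_dates)
    if has_wb and has_plt:
        return "Both"
    if has_wb:
        return "WB"
    if has_plt:
        return "PLT"
    return "None"


@dataclass
class PanelDataset:
    """Cell-level pseudo-panel: one row per retained (section, cohort) cell.

    ``cells`` columns: section, gender, birth_band, history, n_donors,
    total_units, outcome.
    """

    cells: pd.DataFrame
    scheme: CrossSectionScheme = field(default_factory=CrossSectionScheme)
    min_cell_size: int = 30
    label: str = "overall"

    def __post_init__(self):
        missing = [c for c in CELL_COLUMNS if c not in self.cells.columns]
        if missing:
            raise SchemaError(f"cell table missing columns: {missing}", missing)
        if (self.cells["n_donors"] < self.min_cell_size).any():
            raise ValueError("PanelDataset contains cells below min_cell_size")

    def __len__(self) -> int:
        return len(self.cells)

    @property
    def n_cohorts(self) -> int:
        return self.cells.groupby(["gender", "birth_band", "history"]).ngroups

    def cohort_index(self) -> np.ndarray:
        """Integer cohort labels (0..G-1) aligned with ``cells`` rows."""
        key = list(zip(self.cells["gender"], self.cells["birth_band"], self.cells["history"]))
        order = {(c.gender, c.birth_band, c.history): i for i, c in enumerate(all_cohort_keys())}
        codes = np.array([order[k] for k in key])
        # compress to consecutive labels preserving canonical order
        _, inv = np.unique(codes, return_inverse=True)
        return inv

    def to_csv(self, path) -> None:
        self.cells.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, scheme: CrossSectionScheme | None = None,
                 min_cell_size: int = 0, label: str = "overall") -> "PanelDataset":
        # "None" is a real history level, not a missing value
        df = pd.read_csv(path, keep_default_na=False, na_values=[])
        for col in ("section", "n_donors"):
            if col in df.columns:
                df[col] = pd.to_numeric(df[col], errors="coerce").astype("Int64").astype(int)
        for col in ("total_units", "outcome"):
            if col in df.columns:
                df[col] = pd.to_numeric(df[col], errors="coerce")
        missing = [c for c in CELL_COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"{path}: missing columns {missing}", missing)
        return cls(df, scheme or CrossSectionScheme(), min_cell_size, label)


def _check_record_tables(donors: pd.DataFrame, donations: pd.DataFrame) -> None:
    if any(c in donations.columns for c in ("n_donors", "outcome")):
        raise SchemaError(
            "input looks like an aggregated cell table, not donation records; "
            "build_panel requires record-level data")
    missing_d = [c for c in DONOR_COLUMNS if c not in donors.columns]
    missing_r = [c for c in DONATION_COLUMNS if c not in donations.columns]
    if missing_d or missing_r:
        raise SchemaError(
            f"missing columns: donors {missing_d}, donations {missing_r}",
            missing_d + missing_r)
    orphans = set(donations["donor_id"]) - set(donors["donor_id"])
    if orphans:
        some = sorted(map(str, orphans))[:10]
        raise JoinError(f"donations reference unknown donor ids: {some}", some)


def build_panel(donors: pd.DataFrame,
                donations: pd.DataFrame,
                scheme: CrossSectionScheme | None = None,
                min_cell_size: int = 30,
                frd_filter: str = "keep_all",
                history_from_removed: bool = True,
                label: str | None = None) -> PanelDataset:
    """Aggregate donation records into a pseudo-panel of cells.

    Parameters
    ----------
    donors, donations
        Record-level tables with the ``donors.csv`` / ``donations.csv``
        schemas.  Every donation must join to a donor.
    frd_filter
        ``"keep_all"`` retains every donation; ``"drop_frd_pre_ban"`` removes
        family/replacement donations in sections <= ``scheme.ban_breakpoint``
        before grouping (post-ban records are untouched — all post-ban
        donations are voluntary by construction).
    history_from_removed
        When True (default) removed FRD donations still count towards a
        donor's platelet-donation history — the donation event happened, only
        its units are excluded from the outcome — which keeps post-ban cells
        identical between the two filter modes.  When False, history is
        re-derived from the retained records only.
    min_cell_size
        Cells with fewer distinct donors are dropped (measurement-error
        control for the cell means).

    Donation history is evaluated at each section's start date, so a donor
    occupies exactly one cohort within a section but may move to a richer
    history level in later sections.
    """
    scheme = scheme or CrossSectionScheme()
    if frd_filter not in ("keep_all", "drop_frd_pre_ban"):
        raise ValueError(f"unknown frd_filter {frd_filter!r}")
    _check_record_tables(donors, donations)

    rec = donations.copy()
    rec["section"] = scheme.assign_sections(rec["date"])
    first_sec_all = rec.groupby("donor_id")["section"].min()
    if frd_filter == "drop_frd_pre_ban":
        drop = rec["is_frd"].astype(bool) & (rec["section"] <= scheme.ban_breakpoint)
        rec = rec.loc[~drop]

    prof = donors.set_index("donor_id")
    rec = rec.merge(
        prof[["gender", "birth_year", "pre_window_wb", "pre_window_plt"]],
        left_on="donor_id", right_index=True, how="left")

    # first in-window platelet section per donor -> in-window history
    if history_from_removed:
        first_sec = rec["donor_id"].map(first_sec_all)
    else:
        first_sec = rec.groupby("donor_id")["section"].transform("min")
    has_plt = rec["pre_window_plt"].astype(bool) | (rec["section"] > first_sec)
    has_wb = rec["pre_window_wb"].astype(bool)
    history = np.select(
        [has_wb & has_plt, has_wb, has_plt],
        ["Both", "WB", "PLT"], default="None")
    rec["history"] = history
    rec["birth_band"] = pd.cut(
        rec["birth_year"], bins=[1951, 1974, 1984, 2001],
        labels=list(BIRTH_BANDS)).astype(str)
    if (rec["birth_band"] == "nan").any():
        bad = sorted(rec.loc[rec["birth_band"] == "nan", "birth_year"].unique().tolist())
        raise ValueError(f"birth years outside [1952, 2001]: {bad}")

    grouped = (rec.groupby(["section", "gender", "birth_band", "history"], observed=True)
               .agg(n_donors=("donor_id", "nunique"), total_units=("units", "sum"))
               .reset_index())
    grouped["outcome"] = grouped["total_units"] / grouped["n_donors"]
    grouped = grouped.loc[grouped["n_donors"] >= min_cell_size].reset_index(drop=True)
    grouped = grouped.sort_values(["section", "gender", "birth_band", "history"],
                                  ignore_index=True)
    return PanelDataset(grouped[list(CELL_COLUMNS)], scheme, min_cell_size,
                        label or ("voluntary" if frd_filter == "drop_frd_pre_ban" else "overall"))
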