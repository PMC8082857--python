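"""Descriptive before/after-ban comparisons.

Summary-level pooled two-sample t-tests (the before/after contrasts are over
per-cross-section totals: 11 pre-ban vs 3 post-ban values), normal Z-tests on
differences of mean differences or of regression slopes, and one-way ANOVA
with Tukey HSD across donor categories.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class GroupSummary:
    """Sufficient statistics of one group: label, mean, SD, n."""

    label: str
    mean: float
    sd: float
    n: int

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("n must be positive")
        if self.sd < 0:
            raise ValueError("sd must be non-negative")

    @classmethod
    def from_values(cls, label: str, values) -> "GroupSummary":
        v = np.asarray(values, dtype=float)
        return cls(label, float(v.mean()), float(v.std(ddof=1)), len(v))


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: float | None
    p_value: float
    tails: str
    method: str


def pooled_t_test(a: GroupSummary, b: GroupSummary, welch: bool = False) -> TestResult:
    """Two-sample t-test from summary statistics.

    Default is the pooled-variance form:
    ``t = (m_a - m_b) / (s_p * sqrt(1/n_a + 1/n_b))`` with
    ``s_p^2 = ((n_a-1) s_a^2 + (n_b-1) s_b^2) / (n_a + n_b - 2)`` and
    ``df = n_a + n_b - 2``.  ``welch=True`` switches to the unequal-variance
    form with Satterthwaite df.
    """
    if a.n < 2 or b.n < 2:
        raise ValueError("both groups need n >= 2")
    if welch:
        va, vb = a.sd**2 / a.n, b.sd**2 / b.n
        t = (a.mean - b.mean) / np.sqrt(va + vb)
        df = (va + vb) ** 2 / (va**2 / (a.n - 1) + vb**2 / (b.n - 1))
        method = "welch_t"
    else:
        sp2 = ((a.n - 1) * a.sd**2 + (b.n - 1) * b.sd**2) / (a.n + b.n - 2)
        t = (a.mean - b.mean) / np.sqrt(sp2 * (1.0 / a.n + 1.0 / b.n))
        df = a.n + b.n - 2
        method = "pooled_t"
    p = 2.0 * stats.t.sf(abs(t), df)
    return TestResult(float(t), float(df), float(p), "two", method)


def diff_z_test(d1: float, se1: float, d2: float, se2: float,
                tails: str = "two") -> TestResult:
    """Z-test comparing two mean differences (or two regression slopes).

    ``Z = (d1 - d2) / sqrt(se1^2 + se2^2)``.  With ``tails="one"`` the
    statistic is folded to ``|Z|`` and the p-value is the upper normal tail,
    matching the one-sided comparison of two coefficients within one model.
    """
    if se1 <= 0 or se2 <= 0:
        raise ValueError("standard errors must be positive")
    if tails not in ("one", "two"):
        raise ValueError("tails must be 'one' or 'two'")
    z = (d1 - d2) / np.sqrt(se1**2 + se2**2)
    if tails == "one":
        z = abs(z)
        p = stats.norm.sf(z)
    else:
        p = 2.0 * stats.norm.sf(abs(z))
    return TestResult(float(z), None, float(p), tails, "z_diff")


def anova_tukey(groups: dict | list, alpha: float = 0.05):
    """One-way ANOVA with Tukey HSD post-hoc comparisons.

    ``groups`` is a mapping label -> values (or a list of value arrays).
    The F statistic comes from the definitional between/within sums of
    squares; pairwise comparisons use the studentised-range distribution with
    the Tukey-Kramer unequal-n adjustment at the ANOVA residual df.
    Returns ``(TestResult, DataFrame)`` with one row per pair.
    """
    if not isinstance(groups, dict):
        groups = {f"group{i + 1}": v for i, v in enumerate(groups)}
    labels = list(groups)
    arrays = [np.asarray(groups[k], dtype=float) for k in labels]
    if len(arrays) < 2:
        raise ValueError("need at least two groups")
    if any(len(a) < 2 for a in arrays):
        raise ValueError("each group needs n >= 2")

    ns = np.array([len(a) for a in arrays])
    means = np.array([a.mean() for a in arrays])
    grand = np.concatenate(arrays).mean()
    ssb = float((ns * (means - grand) ** 2).sum())
    ssw = float(sum(((a - m) ** 2).sum() for a, m in zip(arrays, means)))
    df_b = len(arrays) - 1
    df_w = int(ns.sum()) - len(arrays)
    msb, msw = ssb / df_b, ssw / df_w
    F = msb / msw
    p = float(stats.f.sf(F, df_b, df_w))
    anova = TestResult(float(F), float(df_b), p, "two", "anova_f")

    rows = []
    for i in range(len(arrays)):
        for j in range(i + 1, len(arrays)):
            diff = means[i] - means[j]
            se = np.sqrt(msw / 2.0 * (1.0 / ns[i] + 1.0 / ns[j]))  # Tukey-Kramer
            q = abs(diff) / se
            p_adj = float(stats.studentized_range.sf(q, len(arrays), df_w))
            rows.append((labels[i], labels[j], float(diff), float(q), p_adj,
                         p_adj <= alpha))
    pairs = pd.DataFrame(rows, columns=["group1", "group2", "mean_diff",
                                        "q_statistic", "p_adj", "significant"])
    return anova, pairs


def before_after_summaries(values_by_section: pd.Series,
                           ban_breakpoint: int = 11) -> tuple[GroupSummary, GroupSummary]:
    """Split a per-section series into before/after summaries for the t-test."""
    s = values_by_section.sort_index()
    pre = s.loc[s.index <= ban_breakpoint]
    post = s.loc[s.index > ban_breakpoint]
    return (GroupSummary.from_values("before", pre.to_numpy()),
            GroupSummary.from_values("after", post.to_numpy()))


def results_table(named_results: dict[str, TestResult]) -> pd.DataFrame:
    """Tidy CSV-ready table (comparison, statistic, df, p, tails, method)."""
    return pd.DataFrame(
        [(k, r.statistic, r.df, r.p_value, r.tails, r.method)
         for k, r in named_results.items()],
        columns=["comparison", "statistic", "df", "p", "tails", "method"])
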