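"""Two-piecewise linear mixed model with cohort random intercepts.

The cell outcome (mean apheresis platelet units per donor, U) is modelled as

    y_{ct} = beta0 + b1 * min(t, k) + b2 * max(t - k, 0) + x_c' gamma
             + max(t - k, 0) * x_c' delta + u_c + e_{ct}

where ``k`` is the policy breakpoint (last pre-ban section), ``x_c`` holds
the cohort's time-invariant covariates (gender, birth band, donation history;
reference levels female / 1952-1974 / None), ``u_c ~ N(0, sigma_u^2)`` is a
cohort random intercept and ``e_{ct} ~ N(0, sigma_e^2)``.  The fitted mean is
continuous in ``t`` at the breakpoint by construction of the split-time basis.

Estimation is restricted maximum likelihood.  With a single random-intercept
variance the covariance is ``V = sigma_e^2 (I + lambda Z Z')`` with
``lambda = sigma_u^2 / sigma_e^2``; beta and sigma_e^2 profile out in closed
form, leaving a one-dimensional restricted likelihood in ``log lambda`` that
is maximised by a coarse multi-start grid followed by Brent refinement, with
an explicit boundary check at ``sigma_u^2 = 0``.  All per-iteration algebra
uses the block (Woodbury) structure of ``Z Z'`` and costs O(n p^2).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import ConvergenceError, RankError
from .pseudo_panel import BIRTH_BANDS, GENDERS, HISTORY_LEVELS, PanelDataset

#: factor expansion: term -> (column suffixes, level test)
_FACTORS = {
    "gender": [("gender[male]", "gender", "male")],
    "birth_band": [(f"birth_band[{b}]", "birth_band", b) for b in BIRTH_BANDS[1:]],
    "history": [(f"history[{h}]", "history", h) for h in HISTORY_LEVELS[1:]],
}

DEFAULT_TERMS = ("intercept", "time_before", "time_after", "gender", "history",
                 "time_after:gender", "time_after:history")
MODEL1_TERMS = ("intercept", "time_before", "time_after")
CANDIDATE_COVARIATES = ("gender", "birth_band", "history")
CANDIDATE_INTERACTIONS = ("time_after:gender", "time_after:history",
                          "gender:history", "time_after:gender:history")


def piecewise_basis(t, k: int):
    """Split-time basis ``(min(t, k), max(t - k, 0))`` for breakpoint ``k``."""
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 1):
        raise ValueError("section index t must be >= 1")
    before = np.minimum(t_arr, k)
    after = np.maximum(t_arr - k, 0.0)
    if np.isscalar(t) or t_arr.ndim == 0:
        return float(before), float(after)
    return before, after


@dataclass(frozen=True)
class PiecewiseDesign:
    """Fixed-effect design: breakpoint plus an ordered term list.

    Terms are ``intercept``, ``time_before``, ``time_after``, the categorical
    covariates ``gender`` / ``birth_band`` / ``history`` (dummy-coded against
    female / 1952-1974 / None), and products thereof joined by ``:``.
    """

    breakpoint: int = 11
    terms: tuple = DEFAULT_TERMS

    def with_terms(self, *extra: str) -> "PiecewiseDesign":
        return PiecewiseDesign(self.breakpoint, tuple(self.terms) + tuple(extra))


def _term_columns(term: str, df: pd.DataFrame, k: int):
    """Expand one (possibly interaction) term into named design columns."""
    tb, ta = piecewise_basis(df["section"].to_numpy(), k)
    base = {"intercept": [("intercept", np.ones(len(df)))],
            "time_before": [("time_before", tb)],
            "time_after": [("time_after", ta)]}
    parts = term.split(":")
    pieces = []  # list of lists of (name, column)
    for p in parts:
        if p in base:
            pieces.append(base[p])
        elif p in _FACTORS:
            pieces.append([(name, (df[col] == level).to_numpy(float))
                           for name, col, level in _FACTORS[p]])
        else:
            raise ValueError(f"unknown design term {p!r}")
    cols = pieces[0]
    for nxt in pieces[1:]:
        cols = [(f"{n1}:{n2}" if n1 != "intercept" else n2, c1 * c2)
                for n1, c1 in cols for n2, c2 in nxt]
    return cols


def design_matrix(cells: pd.DataFrame, design: PiecewiseDesign):
    """Build (X, column names) for the cell table under ``design``."""
    names, columns = [], []
    for term in design.terms:
        for name, col in _term_columns(term, cells, design.breakpoint):
            names.append(name)
            columns.append(col)
    X = np.column_stack(columns) if columns else np.empty((len(cells), 0))
    return X, names


def _check_rank(X: np.ndarray, names: list[str]) -> None:
    r = np.linalg.matrix_rank(X)
    if r < X.shape[1]:
        # identify aliased columns via the QR diagonal
        _, rmat = np.linalg.qr(X)
        diag = np.abs(np.diag(rmat))
        tol = diag.max() * max(X.shape) * np.finfo(float).eps
        aliased = [names[j] for j in range(X.shape[1])
                   if j < len(diag) and diag[j] <= tol] or names
        raise RankError(f"design matrix rank deficient (rank {r} < {X.shape[1]}); "
                        f"aliased: {aliased}", aliased)


@dataclass
class LmmFit:
    """REML fit of the random-intercept model."""

    beta: pd.Series
    se: pd.Series
    sigma2_u: float
    sigma2_e: float
    reml_loglik: float
    blups: pd.Series                     # per-cohort random-intercept predictions
    fitted_marginal: np.ndarray
    fitted_conditional: np.ndarray
    df_resid: int
    design: PiecewiseDesign
    cells: pd.DataFrame
    converged: bool = True
    df_method: str = "residual"
    trace: list = field(default_factory=list, repr=False)

    @property
    def resid_marginal(self) -> np.ndarray:
        return self.cells["outcome"].to_numpy() - self.fitted_marginal

    @property
    def resid_conditional(self) -> np.ndarray:
        return self.cells["outcome"].to_numpy() - self.fitted_conditional


def _group_structure(panel: PanelDataset):
    g = panel.cohort_index()
    n_groups = g.max() + 1
    return g, n_groups


def _profiled_reml(lam: float, X, y, g, n_groups):
    """Profiled restricted log-likelihood pieces at variance ratio ``lam``.

    Returns (minus2_reml_profile, beta, A_inv_scale, sigma2_e, logdet_Vstar,
    logdet_A) where A = X' Vstar^{-1} X and Vstar = I + lam Z Z'.
    """
    n, p = X.shape
    counts = np.bincount(g, minlength=n_groups).astype(float)
    shrink = lam / (1.0 + lam * counts)            # per-group Woodbury factor
    Xg = np.zeros((n_groups, p))
    np.add.at(Xg, g, X)
    yg = np.bincount(g, weights=y, minlength=n_groups)

    A = X.T @ X - (Xg * shrink[:, None]).T @ Xg
    b = X.T @ y - Xg.T @ (shrink * yg)
    beta = np.linalg.solve(A, b)
    r = y - X @ beta
    rg = np.bincount(g, weights=r, minlength=n_groups)
    quad = r @ r - shrink @ rg**2
    sigma2_e = quad / (n - p)
    logdet_V = np.log1p(lam * counts).sum()
    sign, logdet_A = np.linalg.slogdet(A)
    if sign <= 0 or sigma2_e <= 0:
        return np.inf, beta, A, sigma2_e, logdet_V, logdet_A
    m2 = (n - p) * np.log(sigma2_e) + logdet_V + logdet_A
    return m2, beta, A, sigma2_e, logdet_V, logdet_A


def reml_loglik(panel: PanelDataset, design: PiecewiseDesign,
                sigma2_u: float, sigma2_e: float) -> float:
    """Restricted log-likelihood at fixed variance components (GLS beta)."""
    X, _ = design_matrix(panel.cells, design)
    y = panel.cells["outcome"].to_numpy(float)
    g, n_groups = _group_structure(panel)
    n, p = X.shape
    lam = sigma2_u / sigma2_e
    _, beta, A, _, logdet_V, logdet_A = _profiled_reml(lam, X, y, g, n_groups)
    counts = np.bincount(g, minlength=n_groups).astype(float)
    shrink = lam / (1.0 + lam * counts)
    r = y - X @ beta
    rg = np.bincount(g, weights=r, minlength=n_groups)
    quad = (r @ r - shrink @ rg**2) / sigma2_e
    return -0.5 * (n * np.log(sigma2_e) + logdet_V
                   + logdet_A - p * np.log(sigma2_e)
                   + quad + (n - p) * np.log(2 * np.pi))


def fit_reml(panel: PanelDataset, design: PiecewiseDesign | None = None,
             tol: float = 1e-10) -> LmmFit:
    """Fit the random-intercept model by profiled REML.

    The restricted likelihood is profiled down to the variance ratio
    ``lambda = sigma_u^2 / sigma_e^2``; a multi-start grid over ``log lambda``
    seeds Brent refinement, and the boundary ``lambda = 0`` (pure fixed-effect
    model) is always compared.  Deterministic given the data.
    """
    design = design or PiecewiseDesign()
    cells = panel.cells.reset_index(drop=True)
    X, names = design_matrix(cells, design)
    _check_rank(X, names)
    y = cells["outcome"].to_numpy(float)
    g, n_groups = _group_structure(panel)
    if n_groups < 2:
        raise ValueError("need >= 2 cohorts for a random-intercept fit")
    n, p = X.shape

    def objective(log_lam: float) -> float:
        return _profiled_reml(np.exp(log_lam), X, y, g, n_groups)[0]

    grid = np.linspace(-14.0, 8.0, 45)
    vals = np.array([objective(t) for t in grid])
    if not np.isfinite(vals).any():
        raise ConvergenceError("REML objective not finite anywhere on the start grid",
                               list(zip(grid, vals)))
    trace = list(zip(grid.tolist(), vals.tolist()))
    best = int(np.nanargmin(vals))
    lo = grid[max(best - 1, 0)]
    hi = grid[min(best + 1, len(grid) - 1)]
    res = optimize.minimize_scalar(objective, bounds=(lo, hi), method="bounded",
                                   options={"xatol": 1e-12})
    # a second start from the best flanking region guards against grid aliasing
    res2 = optimize.minimize_scalar(
        objective, bounds=(grid[0], grid[-1]), method="bounded",
        options={"xatol": 1e-10})
    cand = min((res, res2), key=lambda r: r.fun)
    trace.append((float(cand.x), float(cand.fun)))

    m2_boundary = _profiled_reml(0.0, X, y, g, n_groups)[0]
    if m2_boundary <= cand.fun + tol:
        lam = 0.0
        m2, beta, A, sigma2_e, logdet_V, logdet_A = _profiled_reml(0.0, X, y, g, n_groups)
    else:
        lam = float(np.exp(cand.x))
        m2, beta, A, sigma2_e, logdet_V, logdet_A = _profiled_reml(lam, X, y, g, n_groups)
    if not np.isfinite(m2):
        raise ConvergenceError("REML objective not finite at the optimum", trace)

    sigma2_u = lam * sigma2_e
    cov = sigma2_e * np.linalg.inv(A)
    se = np.sqrt(np.diag(cov))

    counts = np.bincount(g, minlength=n_groups).astype(float)
    r = y - X @ beta
    rg = np.bincount(g, weights=r, minlength=n_groups)
    blup = lam * rg / (1.0 + lam * counts)

    fitted_marg = X @ beta
    fitted_cond = fitted_marg + blup[g]
    # m2 = (n-p) log sigma2_e + logdet_V + logdet_A; the full restricted
    # log-likelihood adds the exponent term (n-p) and the 2*pi constant
    loglik = -0.5 * (m2 + (n - p) + (n - p) * np.log(2 * np.pi))
    cohort_labels = (cells[["gender", "birth_band", "history"]]
                     .assign(_g=g).drop_duplicates("_g").sort_values("_g"))
    blup_index = [f"{a}/{b}/{c}" for a, b, c in
                  zip(cohort_labels["gender"], cohort_labels["birth_band"],
                      cohort_labels["history"])]
    return LmmFit(
        beta=pd.Series(beta, index=names),
        se=pd.Series(se, index=names),
        sigma2_u=float(sigma2_u),
        sigma2_e=float(sigma2_e),
        reml_loglik=float(loglik),
        blups=pd.Series(blup, index=blup_index),
        fitted_marginal=fitted_marg,
        fitted_conditional=fitted_cond,
        df_resid=n - p,
        design=design,
        cells=cells,
        trace=trace,
    )


def wald_tests(fit: LmmFit) -> pd.DataFrame:
    """Per-coefficient Wald t-tests with residual df = n_cells - rank(X)."""
    stat = fit.beta / fit.se
    p = 2.0 * stats.t.sf(np.abs(stat), fit.df_resid)
    return pd.DataFrame({"term": fit.beta.index, "beta": fit.beta.to_numpy(),
                         "se": fit.se.to_numpy(), "statistic": stat.to_numpy(),
                         "df": fit.df_resid, "p": p}).reset_index(drop=True)


def joint_wald_test(fit: LmmFit, columns: list[str]) -> tuple[float, float]:
    """Joint F-test that all named coefficients are zero. Returns (F, p)."""
    idx = [list(fit.beta.index).index(c) for c in columns]
    b = fit.beta.to_numpy()[idx]
    # covariance sub-block from scaled design; rebuild from stored pieces
    X, _ = design_matrix(fit.cells, fit.design)
    lam = fit.sigma2_u / fit.sigma2_e if fit.sigma2_e > 0 else 0.0
    key = (fit.cells["gender"] + "|" + fit.cells["birth_band"]
           + "|" + fit.cells["history"])
    g = pd.factorize(key)[0]
    counts = np.bincount(g).astype(float)
    shrink = lam / (1.0 + lam * counts)
    Xg = np.zeros((counts.size, X.shape[1]))
    np.add.at(Xg, g, X)
    A = X.T @ X - (Xg * shrink[:, None]).T @ Xg
    cov = fit.sigma2_e * np.linalg.inv(A)
    sub = cov[np.ix_(idx, idx)]
    q = len(idx)
    F = float(b @ np.linalg.solve(sub, b)) / q
    p = float(stats.f.sf(F, q, fit.df_resid))
    return F, p


def predict(fit: LmmFit, gender: str = "female", history: str = "None",
            birth_band: str = BIRTH_BANDS[0], t: float = 1,
            mode: str = "marginal") -> float:
    """Model prediction for one covariate pattern at section ``t``.

    ``marginal`` uses fixed effects only; ``conditional`` adds the cohort's
    BLUP (the cohort must have been present in the fitted panel).
    """
    if gender not in GENDERS or history not in HISTORY_LEVELS or birth_band not in BIRTH_BANDS:
        raise ValueError(f"unseen factor level: {gender}/{birth_band}/{history}")
    row = pd.DataFrame({"section": [t], "gender": [gender],
                        "birth_band": [birth_band], "history": [history]})
    x, names = design_matrix(row, fit.design)
    mu = float((x @ fit.beta.reindex(names).to_numpy())[0])
    if mode == "marginal":
        return mu
    if mode == "conditional":
        key = f"{gender}/{birth_band}/{history}"
        if key not in fit.blups.index:
            raise ValueError(f"cohort {key} absent from the fitted panel")
        return mu + float(fit.blups[key])
    raise ValueError(f"unknown mode {mode!r}")


def pearson_residuals(fit: LmmFit, mode: str = "conditional") -> np.ndarray:
    """Standardised residuals for the diagnostics plots.

    ``marginal``: (y - X beta) / sqrt(sigma_u^2 + sigma_e^2);
    ``conditional``: (y - X beta - Z u_hat) / sigma_e.
    """
    if mode == "marginal":
        return fit.resid_marginal / np.sqrt(fit.sigma2_u + fit.sigma2_e)
    if mode == "conditional":
        return fit.resid_conditional / np.sqrt(fit.sigma2_e)
    raise ValueError(f"unknown mode {mode!r}")


@dataclass
class LadderResult:
    model1: LmmFit
    model2: LmmFit
    model3: LmmFit
    covariates_kept: tuple
    interactions_kept: tuple


def _screen_term(panel, base_design: PiecewiseDesign, term: str, alpha: float,
                 joint: bool) -> bool:
    """True if ``term`` is significant when added to the base design."""
    try:
        fit = fit_reml(panel, base_design.with_terms(term))
    except RankError:
        return False
    base_cols = set(design_matrix(panel.cells.iloc[:1], base_design)[1])
    new_cols = [c for c in fit.beta.index if c not in base_cols]
    if joint:
        _, p = joint_wald_test(fit, new_cols)
        return p <= alpha
    w = wald_tests(fit).set_index("term")
    return bool((w.loc[new_cols, "p"] <= alpha).any())


def model_ladder(panel: PanelDataset, breakpoint: int = 11, alpha: float = 0.05,
                 joint: bool = False) -> LadderResult:
    """Forward model selection: pure trend -> + covariates -> + interactions.

    Model 1 is the unadjusted split-time trend; model 2 adds each candidate
    covariate (gender, birth band, history) that screens significant at
    ``alpha``; model 3 adds significant interaction terms.  Interactions with
    the pre-ban slope are considered only if that slope is itself significant
    in model 2.  A term is retained when its screening p-value is <= alpha.
    """
    d1 = PiecewiseDesign(breakpoint, MODEL1_TERMS)
    fit1 = fit_reml(panel, d1)

    kept_cov = tuple(c for c in CANDIDATE_COVARIATES
                     if _screen_term(panel, d1, c, alpha, joint))
    d2 = d1.with_terms(*kept_cov)
    fit2 = fit_reml(panel, d2)

    w2 = wald_tests(fit2).set_index("term")
    tb_sig = w2.loc["time_before", "p"] <= alpha
    candidates = []
    for term in CANDIDATE_INTERACTIONS:
        factors = [p for p in term.split(":") if p in CANDIDATE_COVARIATES]
        if not all(f in kept_cov for f in factors):
            continue
        candidates.append(term)
        if tb_sig:
            candidates.append(term.replace("time_after", "time_before"))
    # drop duplicates while preserving order
    seen = set()
    candidates = [t for t in candidates if not (t in seen or seen.add(t))]
    kept_int = tuple(t for t in candidates if _screen_term(panel, d2, t, alpha, joint))
    d3 = d2.with_terms(*kept_int)
    fit3 = fit_reml(panel, d3)
    return LadderResult(fit1, fit2, fit3, kept_cov, kept_int)


def fit_summary(fit: LmmFit) -> pd.DataFrame:
    """Tidy per-term summary (term, beta, se, statistic, df, p)."""
    return wald_tests(fit)
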