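"""Piecewise mixed-model machinery: basis, REML, inference, ladder."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from plateletpanel import (GeneratorConfig, PanelDataset, PiecewiseDesign,
                           all_cohort_keys, design_matrix, fit_reml,
                           generate_cell_panel, model_ladder, pearson_residuals,
                           piecewise_basis, predict, wald_tests)
from plateletpanel.errors import RankError
from plateletpanel.piecewise_lmm import MODEL1_TERMS, joint_wald_test, reml_loglik
from plateletpanel.pseudo_panel import CrossSectionScheme
from plateletpanel.synthetic_data import GZ_BETAS


@pytest.mark.parametrize("t, k, expected", [
    (1, 11, (1.0, 0.0)),
    (11, 11, (11.0, 0.0)),   # breakpoint itself belongs to the pre segment
    (12, 11, (11.0, 1.0)),
    (14, 11, (11.0, 3.0)),
])
def test_piecewise_basis(t, k, expected):
    assert piecewise_basis(t, k) == expected


def test_piecewise_basis_rejects_nonpositive_time():
    with pytest.raises(ValueError):
        piecewise_basis(0, 11)


def _one_way_panel(seed=0, g_sd=0.5, e_sd=0.3, m=14):
    rng = np.random.default_rng(seed)
    rows = []
    for c in all_cohort_keys():
        u = rng.normal(0, g_sd)
        for t in range(1, m + 1):
            y = 2.0 + u + rng.normal(0, e_sd)
            rows.append((t, c.gender, c.birth_band, c.history, 100, 100 * y, y))
    df = pd.DataFrame(rows, columns=["section", "gender", "birth_band", "history",
                                     "n_donors", "total_units", "outcome"])
    return PanelDataset(df, CrossSectionScheme(), 0)


def test_reml_matches_closed_form_balanced_anova():
    """On a balanced one-way layout the REML variance components equal the
    closed-form estimators ((MSB - MSW)/m clipped at 0, MSW)."""
    panel = _one_way_panel()
    fit = fit_reml(panel, PiecewiseDesign(11, ("intercept",)))
    y = panel.cells.sort_values(["gender", "birth_band", "history", "section"])
    y = y["outcome"].to_numpy().reshape(24, 14)
    m = 14
    msb = m * np.var(y.mean(axis=1), ddof=1)
    msw = sum(((row - row.mean()) ** 2).sum() for row in y) / (24 * (m - 1))
    s2u_oracle = max((msb - msw) / m, 0.0)
    assert fit.sigma2_e == pytest.approx(msw, rel=1e-6)
    assert fit.sigma2_u == pytest.approx(s2u_oracle, rel=1e-6)


def test_reml_boundary_collapses_to_ols():
    """Data with no cohort effect: sigma2_u hits the boundary and beta equals
    ordinary least squares."""
    panel = generate_cell_panel(GeneratorConfig(seed=3, sigma_u=0.0, sigma_e=0.2))
    fit = fit_reml(panel)
    X, _ = design_matrix(panel.cells, fit.design)
    y = panel.cells["outcome"].to_numpy()
    beta_ols = np.linalg.lstsq(X, y, rcond=None)[0]
    assert fit.sigma2_u < 0.01
    assert np.allclose(fit.beta.to_numpy(), beta_ols, atol=0.02)


def test_reml_objective_beats_grid():
    """The restricted log-likelihood at the optimiser is at least its maximum
    over a 50x50 grid in (log sigma2_u, log sigma2_e) around the optimum."""
    panel = generate_cell_panel(GeneratorConfig(seed=21, sigma_u=0.3, sigma_e=0.3))
    fit = fit_reml(panel)
    at_opt = reml_loglik(panel, fit.design, fit.sigma2_u, fit.sigma2_e)
    assert at_opt == pytest.approx(fit.reml_loglik, abs=1e-6)
    lu = np.log(fit.sigma2_u) + np.linspace(-1.5, 1.5, 50)
    le = np.log(fit.sigma2_e) + np.linspace(-1.5, 1.5, 50)
    grid_best = max(reml_loglik(panel, fit.design, np.exp(a), np.exp(b))
                    for a in lu for b in le)
    assert at_opt >= grid_best - 1e-8


def test_reml_agrees_with_statsmodels():
    """Independent cross-check of the whole fit against MixedLM (REML)."""
    smf = pytest.importorskip("statsmodels.formula.api")
    panel = generate_cell_panel(GeneratorConfig(seed=42, sigma_u=0.3, sigma_e=0.3))
    fit = fit_reml(panel)
    df = panel.cells.copy()
    df["tb"], df["ta"] = piecewise_basis(df["section"].to_numpy(), 11)
    df["male"] = (df["gender"] == "male").astype(float)
    for h in ("WB", "PLT", "Both"):
        df[f"h_{h}"] = (df["history"] == h).astype(float)
    df["cohort"] = df["gender"] + df["birth_band"] + df["history"]
    ref = smf.mixedlm(
        "outcome ~ tb + ta + male + h_WB + h_PLT + h_Both + ta:male "
        "+ ta:h_WB + ta:h_PLT + ta:h_Both", df, groups=df["cohort"]).fit(reml=True)
    assert fit.sigma2_e == pytest.approx(ref.scale, rel=1e-4)
    assert fit.sigma2_u == pytest.approx(ref.cov_re.iloc[0, 0], rel=1e-3)
    assert fit.reml_loglik == pytest.approx(ref.llf, abs=1e-3)
    name_map = {"intercept": "Intercept", "time_before": "tb", "time_after": "ta",
                "gender[male]": "male", "history[WB]": "h_WB",
                "history[PLT]": "h_PLT", "history[Both]": "h_Both",
                "time_after:gender[male]": "ta:male",
                "time_after:history[WB]": "ta:h_WB",
                "time_after:history[PLT]": "ta:h_PLT",
                "time_after:history[Both]": "ta:h_Both"}
    for term, ref_name in name_map.items():
        assert fit.beta[term] == pytest.approx(ref.params[ref_name], abs=1e-8)
        assert fit.se[term] == pytest.approx(ref.bse[ref_name], rel=1e-3)


def test_reference_level_invariance():
    """Swapping which time segment carries the breakpoint column (k = n) must
    reduce to a single straight line, and fitted values never depend on cell
    ordering."""
    panel = generate_cell_panel(GeneratorConfig(seed=8, sigma_u=0.2, sigma_e=0.2))
    fit = fit_reml(panel)
    shuffled = PanelDataset(
        panel.cells.sample(frac=1.0, random_state=0).reset_index(drop=True),
        panel.scheme, 0, panel.label)
    fit2 = fit_reml(shuffled)
    assert fit2.beta.to_numpy() == pytest.approx(fit.beta.to_numpy(), abs=1e-8)
    assert fit2.se.to_numpy() == pytest.approx(fit.se.to_numpy(), abs=1e-8)
    assert fit2.reml_loglik == pytest.approx(fit.reml_loglik, abs=1e-8)


def test_degenerate_breakpoint_reduces_to_single_trend():
    """With k = n_sections there is no post segment; the piecewise model
    equals a one-piece linear trend fit."""
    panel = generate_cell_panel(GeneratorConfig(seed=9, sigma_u=0.2, sigma_e=0.2))
    two_piece = fit_reml(panel, PiecewiseDesign(14, ("intercept", "time_before")))
    # oracle: same model expressed with the raw section index
    df = panel.cells.copy()
    X = np.column_stack([np.ones(len(df)), df["section"].to_numpy(float)])
    # GLS at the two-piece fit's variance ratio must give identical beta
    assert list(two_piece.beta.index) == ["intercept", "time_before"]
    g = panel.cohort_index()
    lam = two_piece.sigma2_u / two_piece.sigma2_e
    counts = np.bincount(g).astype(float)
    shrink = lam / (1 + lam * counts)
    Xg = np.zeros((counts.size, 2))
    np.add.at(Xg, g, X)
    y = df["outcome"].to_numpy()
    yg = np.bincount(g, weights=y)
    A = X.T @ X - (Xg * shrink[:, None]).T @ Xg
    b = X.T @ y - Xg.T @ (shrink * yg)
    assert two_piece.beta.to_numpy() == pytest.approx(np.linalg.solve(A, b), abs=1e-8)


def test_rank_deficiency_reported():
    panel = generate_cell_panel(GeneratorConfig(seed=10, sigma_u=0.1, sigma_e=0.1))
    dup = PiecewiseDesign(11, ("intercept", "time_before", "time_before"))
    with pytest.raises(RankError):
        fit_reml(panel, dup)


def test_prediction_continuity_at_breakpoint():
    """Fitted mean is continuous in t at the breakpoint for every pattern."""
    panel = generate_cell_panel(GeneratorConfig(seed=11, sigma_u=0.2, sigma_e=0.2))
    fit = fit_reml(panel)
    for gender in ("female", "male"):
        for history in ("None", "PLT"):
            left = predict(fit, gender, history, t=11)
            right = predict(fit, gender, history, t=11 + 1e-9)
            assert right == pytest.approx(left, abs=1e-6)


def test_prediction_from_injected_coefficients():
    """A fit whose coefficients are replaced by the reference set must predict
    the hand-computed 5.4426 for (male, PLT, t=14)."""
    panel = generate_cell_panel(GeneratorConfig(seed=1, sigma_u=0.1, sigma_e=0.1))
    fit = fit_reml(panel)
    fit.beta = pd.Series({k: v for k, v in GZ_BETAS.items()}).reindex(fit.beta.index)
    assert predict(fit, "male", "PLT", t=14) == pytest.approx(5.4426, abs=1e-9)
    with pytest.raises(ValueError):
        predict(fit, "male", "unknown", t=2)


def test_conditional_residuals_standardised():
    """Under the true model conditional Pearson residuals have variance near
    one and pass a normality check."""
    pvals, var_ok = [], []
    for r in range(12):
        panel = generate_cell_panel(
            GeneratorConfig(seed=300 + r, sigma_u=0.3, sigma_e=0.3))
        fit = fit_reml(panel)
        res = pearson_residuals(fit, mode="conditional")
        var_ok.append(abs(np.var(res) - 1.0) < 0.15)
        pvals.append(stats.shapiro(res).pvalue)
    assert np.mean(var_ok) >= 0.9
    assert np.mean(np.asarray(pvals) > 0.01) >= 0.9


def test_noiseless_residuals_zero():
    panel = generate_cell_panel(GeneratorConfig(seed=2, sigma_u=0.0, sigma_e=1e-12))
    fit = fit_reml(panel)
    assert np.allclose(pearson_residuals(fit, "marginal")
                       * np.sqrt(fit.sigma2_u + fit.sigma2_e), 0.0, atol=1e-8)


def test_wald_null_term_p_one():
    """A coefficient estimated at exactly zero has p = 1."""
    panel = generate_cell_panel(GeneratorConfig(seed=13, sigma_u=0.1, sigma_e=0.1))
    fit = fit_reml(panel)
    fit.beta["time_after"] = 0.0
    w = wald_tests(fit).set_index("term")
    assert w.loc["time_after", "p"] == pytest.approx(1.0)


def test_joint_wald_consistent_with_single_term():
    panel = generate_cell_panel(GeneratorConfig(seed=14, sigma_u=0.2, sigma_e=0.2))
    fit = fit_reml(panel)
    F, p = joint_wald_test(fit, ["time_after"])
    w = wald_tests(fit).set_index("term")
    assert F == pytest.approx(w.loc["time_after", "statistic"] ** 2, rel=1e-6)


def test_ladder_excludes_null_birth_band():
    """Birth band and the three-way interaction have no effect in the
    generating model and are screened out; the dominant covariate (history)
    and its post-ban interaction survive.  The pre-ban slope is null here, so
    pre-ban interactions are never considered."""
    betas = dict(GZ_BETAS)
    betas.update({"time_before": 0.0, "gender[male]": 0.0,
                  "time_after:gender[male]": 0.0})
    panel = generate_cell_panel(
        GeneratorConfig(seed=77, sigma_u=0.05, sigma_e=0.05, true_betas=betas))
    res = model_ladder(panel)
    assert "birth_band" not in res.covariates_kept
    assert "history" in res.covariates_kept
    assert "time_after:history" in res.interactions_kept
    assert "time_after:gender:history" not in res.interactions_kept
    assert not any(t.startswith("time_before:") for t in res.interactions_kept)


def test_ladder_stops_at_model1_when_all_effects_zero():
    betas = {t: 0.0 for t in GZ_BETAS}
    betas["intercept"] = 2.0
    panel = generate_cell_panel(
        GeneratorConfig(seed=78, sigma_u=0.05, sigma_e=0.05, true_betas=betas))
    res = model_ladder(panel)
    assert res.covariates_kept == ()
    assert res.interactions_kept == ()
    assert tuple(res.model3.design.terms) == MODEL1_TERMS
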