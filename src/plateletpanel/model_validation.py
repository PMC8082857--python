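"""Model validation: k-fold cross-validation, over-fitting ratio, R-squared.

Cells are partitioned into ``k`` random folds of near-equal size; each fold is
predicted from a model fitted on the rest using fixed effects only (a scored
new observation carries no realised cohort effect).  The combined
cross-validation error is the root of the mean squared per-fold RMSE,
``sqrt((RMSE_1^2 + ... + RMSE_k^2) / k)``, and over-fitting is quantified as
the relative excess of that combined RMSE over the full-sample training RMSE.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .piecewise_lmm import LmmFit, PiecewiseDesign, design_matrix, fit_reml
from .pseudo_panel import PanelDataset


@dataclass
class CvResult:
    fold_rmse: np.ndarray
    combined_rmse: float
    train_rmse: float
    overfit_pct: float
    seed: int
    fold_assignment: np.ndarray
    holdout_predictions: pd.DataFrame = field(repr=False, default=None)

    def to_dict(self) -> dict:
        return {"fold_rmse": [float(v) for v in self.fold_rmse],
                "combined_rmse": float(self.combined_rmse),
                "train_rmse": float(self.train_rmse),
                "overfit_pct": float(self.overfit_pct),
                "seed": int(self.seed)}


def combine_rmse(fold_rmse) -> float:
    """Combined CV error: sqrt of the mean of squared per-fold RMSEs."""
    r = np.asarray(fold_rmse, dtype=float)
    return float(np.sqrt(np.mean(r**2)))


def overfit_pct(combined_rmse: float, train_rmse: float) -> float:
    """Relative excess of CV error over training error, in percent."""
    if train_rmse <= 0:
        raise ValueError("train_rmse must be positive to define over-fitting")
    return 100.0 * (combined_rmse - train_rmse) / train_rmse


def kfold_cv(panel: PanelDataset, design: PiecewiseDesign | None = None,
             k: int = 5, seed: int = 0, mode: str = "marginal") -> CvResult:
    """k-fold cross-validation of the mixed model on the cell panel.

    Folds are a uniform random partition with sizes differing by at most one.
    Held-out cells are scored with ``mode="marginal"`` (fixed effects only,
    default) or ``"conditional"`` (adds the training fit's cohort BLUP when
    the cohort was present in training).
    """
    design = design or PiecewiseDesign()
    cells = panel.cells.reset_index(drop=True)
    n = len(cells)
    if n < k:
        raise ValueError(f"need at least k={k} cells, got {n}")
    rng = np.random.default_rng(seed)
    assignment = rng.permutation(np.arange(n) % k)

    fold_rmse = np.zeros(k)
    preds = np.full(n, np.nan)
    for fold in range(k):
        test = assignment == fold
        train_panel = PanelDataset(cells.loc[~test].reset_index(drop=True),
                                   panel.scheme, 0, panel.label)
        try:
            fit = fit_reml(train_panel, design)
        except Exception as exc:
            raise type(exc)(f"fold {fold}: {exc}") from exc
        test_cells = cells.loc[test]
        X, names = design_matrix(test_cells, design)
        yhat = X @ fit.beta.reindex(names).to_numpy()
        if mode == "conditional":
            keys = [f"{g}/{b}/{h}" for g, b, h in zip(
                test_cells["gender"], test_cells["birth_band"], test_cells["history"])]
            yhat = yhat + np.array([fit.blups.get(key, 0.0) for key in keys])
        preds[test] = yhat
        fold_rmse[fold] = np.sqrt(np.mean((test_cells["outcome"].to_numpy() - yhat) ** 2))

    full_fit = fit_reml(panel, design)
    train_rmse = float(np.sqrt(np.mean(full_fit.resid_marginal**2)))
    combined = combine_rmse(fold_rmse)
    pct = overfit_pct(combined, train_rmse) if train_rmse > 0 else float("nan")
    holdout = cells[["section", "gender", "birth_band", "history", "outcome"]].copy()
    holdout["fold"] = assignment
    holdout["prediction"] = preds
    return CvResult(fold_rmse, combined, train_rmse, pct, seed, assignment, holdout)


def r_squared(fit: LmmFit) -> float:
    """Explained-variance measure ``1 - SSE / (SSE + SSR)``.

    SSE is the sum of squared conditional (unscaled) residuals and SSR the
    sum of squared centred conditional fitted values.
    """
    sse = float(np.sum(fit.resid_conditional**2))
    fitted = fit.fitted_conditional
    ssr = float(np.sum((fitted - fitted.mean()) ** 2))
    if sse + ssr == 0:
        raise ValueError("constant outcome: R^2 undefined")
    return 1.0 - sse / (sse + ssr)
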