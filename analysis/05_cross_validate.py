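#!/usr/bin/env python
"""Five-fold cross-validation of the fitted model.

Cells are split into five random folds; each is predicted (fixed effects
only) from a fit on the other four.  Reports per-fold RMSE, the combined
RMSE sqrt(mean(RMSE_i^2)), and the over-fitting percentage relative to the
full-sample training RMSE.  Writes cv.json and cv_predictions.csv.
"""

import json
from pathlib import Path

from plateletpanel import PanelDataset, kfold_cv

OUT = Path(__file__).resolve().parent.parent / "results" / "analysis"
SEED = 1


def main() -> None:
    panel = PanelDataset.from_csv(OUT / "cells.csv")
    cv = kfold_cv(panel, k=5, seed=SEED)
    for i, r in enumerate(cv.fold_rmse, 1):
        print(f"fold {i}: RMSE {r:.4f} U")
    print(f"combined RMSE {cv.combined_rmse:.4f} U, "
          f"training RMSE {cv.train_rmse:.4f} U, "
          f"over-fitting {cv.overfit_pct:.2f}%")
    (OUT / "cv.json").write_text(json.dumps(cv.to_dict(), indent=2) + "\n")
    cv.holdout_predictions.to_csv(OUT / "cv_predictions.csv", index=False)


if __name__ == "__main__":
    main()
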