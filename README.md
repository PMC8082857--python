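# plateletpanel

Pseudo-panel trend analysis of plateletpheresis (apheresis platelet)
donations around China's nationwide ban on family/replacement donation
(FRD), effective 2018-04-01.

Blood centres record donations as repeated cross-sections: different donors
appear in different half-year windows, so individual-level longitudinal
models do not apply directly. The pseudo-panel approach groups donors on
time-invariant covariates — gender, birth-year band (1952–1974 / 1975–1984 /
1985–2001), and blood-donation history (None / WB / PLT / Both) — into
2 × 3 × 4 = 24 cohorts observed over 14 six-month cross-sections
(2012-10 … 2019-09), i.e. up to 336 cells. Each cell's outcome is the mean
apheresis platelet units per distinct donor (U). Cells with fewer than 30
donors are dropped to control measurement error.

The trend model is a two-piecewise linear mixed model with a fixed breakpoint
at the last pre-ban cross-section (k = 11) and a cohort random intercept:

    y_ct = β₀ + β₁·min(t, k) + β₂·max(t − k, 0) + x_c'γ
           + max(t − k, 0)·x_c'δ + u_c + ε_ct,
    u_c ~ N(0, σ²_u),   ε_ct ~ N(0, σ²_e)

so the fitted mean is continuous at the breakpoint, β₁ is the pre-ban slope
and β₂ the post-ban slope for the reference cohort (female, no history),
with interactions δ letting the post-ban slope differ by gender and history.
Estimation is restricted maximum likelihood, profiled down to the variance
ratio λ = σ²_u/σ²_e (grid + Brent refinement with a boundary check at
σ²_u = 0); inference is Wald with residual degrees of freedom. The package
also provides the forward model ladder (pure trend → + significant
covariates → + significant interactions), five-fold cross-validation with
the combined error √(mean RMSE²_fold), Pearson residual diagnostics,
summary-level pooled t / Z tests and ANOVA + Tukey HSD, and the FRD-removal
sensitivity analysis (drop pre-ban FRD donations, re-group, refit, contrast
pre-ban slopes).

Because the centres' individual-level records are not public, the package
ships a synthetic-data generator with known ground truth at two levels: cell
level (draws cell means directly from the model above) and registry level
(simulates donors and donation events — entry, retention, FRD propensity,
per-donation units in {1, 1.5, 2} U, and the 24-collections-per-rolling-year
cap) so every pipeline stage is testable end to end.

## Worked example

```python
from plateletpanel import (GeneratorConfig, generate_registry, build_panel,
                           fit_reml, wald_tests, kfold_cv)

cfg = GeneratorConfig(n_donors=12000, seed=1)
donors, donations = generate_registry(cfg)
panel = build_panel(donors, donations, cfg.scheme, min_cell_size=30)
fit = fit_reml(panel)
print(wald_tests(fit).round(4).to_string(index=False))
```

prints (abridged)

```
        term   beta     se  statistic  df      p
   intercept 1.9528 0.0526    37.1123 226 0.0000
 time_before 0.0380 0.0057     6.6998 226 0.0000
  time_after 0.5796 0.0448    12.9271 226 0.0000
gender[male] 0.1284 0.0373     3.4473 226 0.0007
history[PLT] 0.2227 0.0438     5.0836 226 0.0000
...
```

Here 232 of the 336 possible cells reach 30 donors; the post-ban slope
(`time_after`, 0.58 U per half-year for the reference cohort) far exceeds
the pre-ban slope (0.038), male donors and donors with platelet history have
higher baseline outcomes, and `kfold_cv(panel, seed=1)` reports a combined
cross-validation RMSE of 0.25 U against a training RMSE of 0.24 U
(over-fitting ≈ 7%). The same registry shows the fewer-donors-more-blood
pattern: per-section donor totals fall after the ban while donation and unit
totals rise.

The numbered scripts under `analysis/` run the same pipeline as a narrative
sequence (simulate → build panel → descriptives → fit → cross-validate →
FRD sensitivity), writing tables under `results/analysis/`. The same stages
are available as a CLI: `plateletpanel all --seed 1 --outdir results/run`.

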