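# Methods

## Study design being modelled

Plateletpheresis donation records from a large blood centre are observed as
14 repeated cross-sections of six months each, spanning 2012-10-01 to
2019-09-30. A nationwide ban on family/replacement donation (FRD) opens the
12th cross-section (2018-04-01), so the series has 11 pre-ban and 3 post-ban
windows. Donors may recur across windows (the national standard allows up to
24 plateletpheresis collections per rolling 12 months), which gives the data
a pseudo-panel rather than an independent cross-sectional structure.

## Pseudo-panel construction

Donors are grouped on three time-invariant covariates: gender (male/female),
birth-year band (1952–1974, 1975–1984, 1985–2001; boundaries inclusive), and
blood-donation history evaluated at the start of each cross-section — None,
whole-blood only (WB), apheresis platelet only (PLT), or Both. This yields
2 × 3 × 4 = 24 cohorts per cross-section, up to 336 cells. The cell outcome
is total apheresis units divided by the number of distinct donors in the
cell (U per donor). Cells with fewer than 30 distinct donors are removed
(default `min_cell_size=30`), a measurement-error control for cell means.

Conventions that the construction fixes:

- Cross-sections are half-open calendar intervals `[start, end)`; no
  time-of-day.
- History uses events *strictly before the section's start date* (not before
  each donation), so a donor occupies exactly one cohort within a section; a
  first-time donor stays `None` for the whole entry section even when
  donating twice in it. History is therefore monotone over sections
  (None → {WB, PLT} → Both).
- The data are left-truncated at the window start, so donor profiles carry
  explicit pre-window whole-blood/platelet flags; in-window whole-blood
  donations are out of scope (whole-blood history can only enter through the
  flag).

## The piecewise linear mixed model

With `t = 1..14` the section index and `k = 11` the breakpoint, the
split-time basis is `time_before = min(t, k)`, `time_after = max(t − k, 0)`,
which makes the fitted mean continuous at the breakpoint by construction.
The full (reference) design is

    outcome ~ intercept + time_before + time_after + gender + history
              + time_after:gender + time_after:history

with reference levels female / 1952–1974 / None and a cohort random
intercept. Time is the raw section index, uncentred, so the intercept is the
extrapolated section-0 level for the reference cohort. A single random
intercept with an unstructured covariance reduces to one scalar variance
σ²_u; it is implemented as such. Cells are unweighted (each cell is one
observation); donor-count weights would be a straightforward extension but
are not used by default.

### Estimation

Restricted maximum likelihood. Writing V = σ²_e (I + λ ZZ') with
λ = σ²_u/σ²_e and Z the cohort indicator matrix, β and σ²_e profile out in
closed form and the restricted likelihood becomes one-dimensional in log λ.
Each objective evaluation uses the block (Woodbury) structure of ZZ' — per
cohort g of size n_g, V*⁻¹ subtracts λ/(1 + λ n_g) times the group-sum
outer product, and log|V*| = Σ log(1 + λ n_g) — so an evaluation costs
O(n p²). The optimiser is a 45-point grid over log λ ∈ [−14, 8] followed by
bounded Brent refinement (two starts), always compared against the boundary
λ = 0 (which collapses to ordinary least squares). Convergence tolerance is
~1e-12 on log λ; the optimisation is deterministic given the data. The fit
matches statsmodels `MixedLM` (REML) to machine precision on β, SE, both
variance components, and the restricted log-likelihood (verified in the test
suite; statsmodels is a cross-check only, not the implementation).

### Inference

Wald t-tests with residual degrees of freedom `df = n_cells − rank(X)`. SAS
PROC MIXED (used in the original analyses of this design) defaults to a
containment/between-within df method, so p-values can differ in the third
decimal on small panels; the residual-df choice is simple, conservative
enough at 200+ cells, and documented in the fit object (`df_method`). A
joint F-test over a set of coefficients is available for factor-level
screening. Coefficient comparisons within one model use the normal Z on the
difference scaled by the root-sum-square of the SEs (one-tailed by
convention for ordered hypotheses).

Note a reference-table inconsistency carried in the literature this model
family comes from: the intercept for the Guangzhou-range coefficient set is
printed as 0.8636 in the coefficient table and 0.8630 in the accompanying
model equation (similarly 2.6243 vs 2.6242 for the PLT effect). The
package's `GZ_BETAS` uses the table-body values, which are the combination
consistent with the worked prediction 5.4426 U for (male, PLT, t = 14).

### Model ladder

Forward selection: model 1 is the unadjusted split-time trend; model 2 adds
each candidate covariate (gender, birth band, history) that is significant
when added alone to model 1; model 3 adds interaction candidates
(time_after×gender, time_after×history, gender×history, and the three-way
time_after×gender×history) that are significant when added to model 2.
Interactions with `time_before` are considered only when the pre-ban main
slope is itself significant in model 2. A term is retained when its
screening p ≤ α (α = 0.05); for multi-level factors the per-level Wald test
is used (any level significant retains the factor), with the joint F
variant available via `joint=True`.

A structural caveat: with only 24 cohorts, one-at-a-time screening of a
between-cohort covariate competes against all *unmodelled* cohort
heterogeneity, which is absorbed by the random intercept. A gender effect of
~1.3 U cannot screen significant while history effects of ~2.6–3.9 U remain
unmodelled (the implied SE is ~0.7 regardless of residual noise). This is a
property of the stated selection rule, not of the implementation; screening
within the full covariate model avoids it but is not the documented rule.

## Validation

- **Five-fold cross-validation.** Cells are partitioned uniformly at random
  into folds whose sizes differ by at most one (seeded, recorded in the
  output). Held-out cells are scored with fixed effects only — a scored
  "new" observation carries no realised cohort effect, matching a
  store-and-score workflow; conditional scoring (adding the training BLUP
  for cohorts seen in training) is available as an option. The combined
  error is `sqrt((RMSE₁² + … + RMSE₅²)/5)`.
- **Over-fitting percentage** is defined here as
  `100·(combined_RMSE − train_RMSE)/train_RMSE`, with the training RMSE the
  raw marginal residual RMSE of the full-sample fit (raw, not REML-scaled;
  marginal on both sides for comparability). This is an interpretation — the
  quantity is conventionally reported without a formula.
- **R²** is `1 − SSE/(SSE + SSR)` with SSE the sum of squared conditional
  (unscaled) residuals and SSR the sum of squared centred conditional fitted
  values.
- **Pearson residuals**: marginal `(y − Xβ̂)/√(σ̂²_u + σ̂²_e)` and
  conditional `(y − Xβ̂ − Zû)/σ̂_e`.

## FRD-removal sensitivity analysis

Pre-ban FRD donations are removed record-wise; donors remain in a cell if
any voluntary donation remains, and cells may fall below the size threshold
and disappear. By default removed FRD events still count toward a donor's
donation *history* (the donation happened; only its units are excluded from
the outcome), which guarantees the post-ban cells are byte-identical between
the overall and voluntary analyses — post-ban donations are all voluntary,
so nothing after the breakpoint changes. Setting
`history_from_removed=False` re-derives history from retained records only;
this changes post-ban cohort membership for donors whose only pre-ban
donations were FRD and is provided for exploring that alternative reading.
The analysis reports both pre-ban slopes with SEs and a two-sided normal
contrast (independent-fits approximation — the two panels share data, so the
contrast is descriptive rather than exact).

## Synthetic-data generator

Defaults are the study conditions and are not tuned per experiment.

**Cell level** (`generate_cell_panel`) draws each of the 336 cell outcomes
directly from the mixed model: `μ(cohort, t)` from a configurable
coefficient set (`GZ_BETAS`/`CD_BETAS`, magnitudes matching the two-centre
setting; birth-band effects default to zero), plus cohort effects
`N(0, σ²_u)` and cell noise `N(0, σ²_e)` with σ_u = σ_e = 0.3 U by default;
simulated donor counts are Poisson(300)+30. This level isolates the
estimator from aggregation effects.

**Registry level** (`generate_registry`) simulates donors and events:

- One root seed; donor *i* uses the child stream `SeedSequence(seed,
  spawn_key=(i,))`, so enlarging a registry never perturbs existing donors.
- Entry section is drawn with pre-ban sections up-weighted by
  `1 + 1.5 × FRD share` (family/replacement recruitment brings in extra
  first-time donors that the ban later removes). Gender is Bernoulli(0.73
  male); birth year is uniform within the drawn band intersected with the
  18–60 age eligibility at entry; entry history flags follow a configurable
  mix (52/15/20/13% None/WB/PLT/Both).
- A persistent latent uniform per donor marks the donor as FRD in section s
  exactly when it falls below the configured FRD share (defaults follow the
  observed Guangzhou trajectory 15.4% → 41.9% over the first ten sections,
  18.5% in the announcement half-year, zero after the ban). This makes
  section margins match the configured fractions while keeping FRD status
  donor-sticky, reflecting that FRD status is recorded per donation but
  driven by donor-level circumstances.
- Voluntary donor-sections contribute `1 + Poisson(rate)` donations, the
  rate rising slowly pre-ban (0.035/section) and faster post-ban
  (0.25/section), boosted for male (+0.15) and donation-experienced donors
  (+0.30 platelet, +0.05 whole-blood) — the improved-donation-behaviour
  mechanism. FRD donor-sections contribute a single donation. Units per
  donation are 1/1.5/2 U with probabilities (0.25, 0.45, 0.30) for voluntary
  and (0.70, 0.25, 0.05) for FRD donations (FRD donors give smaller
  volumes). Retention to the next section is 0.55 for voluntary and 0.30
  after an FRD section. A rolling 365-day cap of 24 collections is enforced
  record-wise.

These mechanics reproduce the study's qualitative structure: fewer donors
but more donations and units after the ban; FRD < voluntary-pre-ban <
voluntary-post-ban in per-donor units; a flattened overall pre-ban trend
that steepens when FRD records are removed. What the generator does **not**
emulate: seasonal and holiday donation patterns, centre-level operational
shocks, donor ageing across bands, measurement error in units, in-window
whole-blood donations, and any dependence of FRD propensity on demographics.
Passing tests therefore demonstrate correctness of the statistical machinery
and of directional, mechanism-level claims — not that real donation data
satisfy the model.

## Numerical and degenerate-input choices

- Variance optimisation tolerances as above; σ²_u is reported as exactly the
  boundary value 0 when the boundary beats the interior optimum.
- Rank-deficient designs raise an error listing aliased columns (QR
  diagonal); orphan donations, out-of-window dates, and missing columns
  raise typed errors naming the offending items.
- `sigma_e = 0` is disallowed in the generator config; "noiseless" test
  panels use `sigma_e = 1e-12`.
- Ties in ladder screening at exactly p = α retain the term.
- CSV round-trips treat `"None"` as a genuine history level, never as a
  missing value; dates are ISO-8601, UTF-8, `.` decimal.

## Problem sizes used by the test and acceptance runs

Simulation-based checks use 336-cell panels (the full crossing), 200–500
replicates for recovery/coverage studies, 1000 replicates for null
calibration, and registries of 8,000–12,000 donors — sizes chosen so the
Monte-Carlo error of each checked quantity is several times smaller than its
assertion tolerance.

## Known limitations

- Residual df for Wald tests (not Satterthwaite/Kenward-Roger); negligible
  at 200+ cells, visible on tiny panels.
- The breakpoint is fixed a priori by the policy date; no breakpoint
  estimation, and no serial-correlation structures beyond the cohort random
  intercept.
- The per-coefficient post-ban slope test has low power at the default
  generator noise (its SE on the 336-cell design is ≈0.042 at
  σ_u = σ_e = 0.3); detecting a 0.04 U/section effect with high power
  requires either the joint post-ban block test or residual noise well below
  0.1 U.
- The sensitivity slope contrast treats the two fits as independent although
  they share records.
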