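# Methods

## The problem

Overlapping panel surveys field a fresh probability sample at every
measurement occasion and keep re-interviewing everyone recruited
earlier, so the effective sample of occasion `M_j` is the union of the
survivors of panels `P_1..P_{j-1}` plus the fresh respondents of
`M_j`. Two error sources accumulate: unit non-response at first
contact and attrition between occasions, both typically covariate-
dependent, so naive respondent means are biased for the closed target
population. `panelcal` implements a two-step correction — per-
component response-propensity reweighting followed by calibration to
known population margins — together with the full family of
cross-sectional and longitudinal estimators and BCa bootstrap
intervals.

## Sampling model and notation

A closed finite population `U` of size `N`, stratified by province ×
urbanization grade (`L` strata, sizes `N_h`). The new sample `s^(j)`
of occasion `j` is a stratified SRS with allocation proportional to
`N_h` (largest-remainder rounding, ties by stratum label order), drawn
disjoint from all earlier new samples. `δ` indicates response; the
effective sample `s_r^(i,j)` of panel `i` at occasion `j` contains the
units of `s^(i)` that responded at *every* occasion `M_i..M_j`. A unit
that skips an occasion leaves its panel's effective samples for good,
even if it would have returned later; re-admission behaviour of real
fieldwork is ambiguous and this strict survivorship rule matches the
estimator definitions.

## Weighting stages

1. **Design weights.** `d_k = N_h / n_h^(j)`, the inverse inclusion
   probability; self-weighting (`N/n^(j)`) under exactly proportional
   allocation.
2. **Response-rate adjustment** (the pre-model baseline, also used as
   the comparison arm in the bias studies): respondent weights divided
   by `r = n_r/n`, computed per stratum by default (strata are the
   response-homogeneity classes) or overall by configuration.
3. **Propensity-score adjustment (PSA).** Response of each component
   is modelled as ignorable, `P(δ=1 | y, x) = m(x, λ)`. The model for
   the new sample `s^(j)` trains on all its theoretical-sample units
   with frame covariates; the model for panel `i` at `j` trains on the
   survivors `s_r^(i,j-1)` and may additionally use their outcomes
   observed up to `j-1` (default on). Training uses class-balancing
   instance weights `(1-p)δ + p(1-δ)` (`p` = observed response rate),
   and the distorted scores are mapped back with
   `π̂_corr = π̂p / (π̂p + (1-π̂)(1-p))` — the identity at `p = 0.5`,
   strictly increasing in `π̂`. Corrected propensities are clipped to
   `[0.02, 0.98]` to bound weight inflation; the bound is exposed in
   configuration because published practice rarely reports one.
   The PSA weights are
   `d_k^(j),PSA = (N_h/n_h^(j)) (n^(j)/n_r^(j)) / π̂_k` for the fresh
   sample and `(N/n_r^(i,j-1)) (n_r^(i,j-1)/n_r^(i,j)) / π̂_k` for
   panel components. Both carry the observed attrition factor *and*
   `1/π̂`, so component totals are deliberately over-scaled (≈ `N·n/n_r`);
   the calibration step re-normalizes the scale, and no total is
   reported pre-calibration.
4. **Combination.** The cross-sectional estimator at `j` is the convex
   combination `Σ α_i Ŷ^PSA_i` with `α_i` equal to each component's
   share of the total effective sample at `j` — outcome-free by
   construction. Scaling each component's weights by its `α` gives one
   combined vector `D_k^(j)` over the disjoint union.
5. **Calibration.** Truncated raking (multiplicative IPF) adjusts
   `D_k` so weighted totals match population margin totals for sex
   crossed with age group, province, urbanization and nationality —
   four separate cross-classifications, not one interaction table.
   After each full cycle the ratio `w_k/D_k` is clamped to
   `[L, U] = [0.3, 3.0]` (configurable; the bounds used by statistics
   institutes are generally unpublished) and cycling continues until
   every margin's relative error is below `1e-8` or 500 cycles; on
   non-convergence weights are returned with a warning diagnostic. A
   linear-distance (GREG) solution in closed form is available for
   cross-checks; truncation does not apply to it.

Longitudinal weights `v_k^(j,j-1)` take the panel components only
(excluding the fresh sample at `j`), combine them with the same
effective-share rule, and calibrate against the same margins; the
margins of the published studies' longitudinal step are not stated, so
re-using the cross-sectional margins is this package's choice.

## Estimators

From calibrated cross-sectional weights `w`: totals `Σ w y`, class
proportions, absolute and relative change vs. the first measurement,
absolute gender gap (women minus men) and relative gender gap (gap
over the men's value). From longitudinal weights `v`: the weighted
within-unit difference `Σ v (y^(j) - y^(j-1))`, gross-change counts
over a class `A ∈ {increase, decrease, same}` (for continuous
outcomes "same" means `|diff| ≤ ε`, default `ε = 0` since the
motivating outcome is ordinal), the deterioration/improvement rate
`(θ^dec - θ^inc)/θ^inc`, and gender gaps of each class count. All
ratio estimators raise on zero denominators rather than returning
non-finite values. Gender gaps are reported signed, positive = larger
among women; polarity interpretation depends on the outcome.

## Propensity model families and hyperparameter search

The default family is gradient boosted trees (XGBoost) with the
search space: number of trees [10, 1000], learning rate [0.001, 0.9]
(sampled on a log scale), maximum depth [1, 30], minimum child weight
[0, 10], subsample fraction [0.6, 1]. Candidates are scored by 5-fold
label-stratified cross-validated weighted logistic loss (folds share
the overall δ proportion; fold assignment is seeded). The search is a
seeded randomized search over that space with a default budget of 50
candidates; randomized search over a bounded space is a strong,
reproducible baseline for sequential model-based optimizers at this
budget, and the winning configuration is refit on all rows with the
class-balance weights. Logistic regression is provided as a fast,
deterministic family and is the one used in the replicated bias and
coverage studies, where thousands of fits are needed.

## Variance estimation

Confidence intervals are bias-corrected and accelerated (BCa)
percentile bootstrap. Units are resampled with replacement within
(panel × stratum) blocks — the theoretical-sample level — carrying
their entire response trajectory, so attrition variability propagates
into the replicates; block sizes are preserved, keeping design
weights valid on replicates. The median-bias term is
`z0 = Φ⁻¹(#{θ* < θ̂}/B)` (the fraction clipped away from 0 and 1 by
half a replicate), and the acceleration is the jackknife skewness
`a = Σ(θ̄-θ_i)³ / (6 [Σ(θ̄-θ_i)²]^{3/2})` over leave-one-unit-out
estimates. Degenerate replicate distributions return a zero-width
interval with a warning flag. Refitting propensity models inside each
replicate is optional: on for the logistic family, off by default for
the boosted family, where re-scoring by the original model trades a
known variance underestimation for tractable cost.

## The synthetic study

The bundled generator emulates a four-measurement regional health
panel at desk scale: `N = 20 000` closed population, 8 strata (4
provinces × 2 urbanization grades, urban-heavy shares), calibration
attributes sex (1:1), age group (0.30/0.40/0.30), nationality
(0.90/0.10), covariates `x1, x2 ~ N(0,1)` with `x1` shifted by ±0.5
by age group so age carries outcome signal. Outcomes follow
`y^(j) = shift_j + βx + 0.3·1{woman} + noise` with per-measurement
shifts (0, 0.15, 0.35, 0.5) emulating a worsening trend; the ordinal
variant cuts a logistic latent at (-1.5, -0.5, 0.7, 1.8) into five
categories (1 best .. 5 worst, dichotomized 4-5 = poor). Theoretical
new-sample sizes (750, 640, 750, 750) keep the second occasion
smaller, mirroring the shape of the motivating survey at roughly
one-fifth scale; response rates are 0.7 for fresh contact and 0.8 per
follow-up, MAR-logistic in `x1` (coefficient -0.8) with the intercept
solved by root-finding so the marginal rate hits the target to 1e-6.

What the generator does **not** emulate: births/deaths/migration
(open populations are a stated non-goal), item non-response,
measurement error in the ordinal scale, interviewer/mode effects, and
real frames' undercoverage. Passing tests therefore demonstrate
correctness of the estimators and the bias-reduction mechanism under
ignorable covariate-driven non-response — not robustness to
non-ignorable missingness.

## Validation studies and problem sizes

The replicated studies (in `panelcal.studies`, also re-run by
`scripts/acceptance.py`) use desk-scale sizes chosen to keep each
study in the minutes range on one core: HT unbiasedness at
`N = 10 000`, `n = 400`, 2 000 replicates; MAR bias reduction on a
`t = 3` panel, `N = 5 000`, 500 replicates with the logistic family;
BCa coverage on full-response designs, `N = 5 000`, `n = 150`,
400 intervals at `B = 400`. Under full response the weighting chain
collapses to design weights plus calibration, and exactly that
reduced chain (through the package's raking core) is re-executed for
every bootstrap replicate and jackknife evaluation of the coverage
study.

## Numerical choices

- Largest-remainder apportionment everywhere an integer allocation is
  needed; ties broken by label order for reproducibility.
- IPF processes margins in their configured order; order is fixed so
  runs are bit-reproducible.
- The low-level raking core skips margin cells absent from the sample
  (bootstrap replicates can lose a rare cell); the user-facing
  calibrator treats such cells as infeasible and raises, naming them.
- One global seed fans out into per-stage seeds through
  `SeedSequence([seed, stage tags...])`, so any stage can be re-run in
  isolation with identical results.
- Proportions are exact ratios of weighted totals; no smoothing.

## Known limitations

- Panel PSA weights correct each panel's latest transition; earlier
  attrition is carried through the observed survivor counts, so
  residual bias remains when non-response is strongly covariate-
  dependent over several occasions (visible in the MAR study: the
  bias ratio is ≈ 0.45, a halving rather than an elimination).
- Truncated raking with tight bounds may legitimately fail to reach
  the margins; the diagnostics report this rather than silently
  accepting the result.
- BCa intervals with propensity refitting disabled underestimate the
  model-fitting contribution to variance.
- The MCAR fallback (constant propensity) is used automatically when
  a component's labels are single-class, e.g. under full response.
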