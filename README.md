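# panelcal

Reweighting, calibration and estimation for **overlapping panel
surveys** affected by non-response.

In an overlapping panel design every measurement occasion `M_j` fields
a fresh stratified probability sample *and* re-interviews everyone
recruited at earlier occasions, so the effective sample of `M_j` is
`s_r^{M_j} = ∪_i s_r^{(i,j)} ∪ s_r^{(j)}` — the survivors of each
panel plus the fresh respondents. First-contact non-response and
panel attrition are both covariate-dependent in practice, which
biases naive respondent estimates. `panelcal` implements a two-step
correction:

1. **Propensity-score adjustment (PSA)** per sample component:
   response `δ` is modelled as ignorable, `P(δ=1|y,x) = m(x, λ)`,
   with class-balanced gradient boosted trees (or logistic
   regression), the balance-corrected propensity
   `π̂p / (π̂p + (1-π̂)(1-p))`, and weights
   `d_k (n/n_r) / π̂_k` per component;
2. **truncated raking calibration** of the convex combination
   `D_k^(j) = α_i · d_k^{PSA}` (`α_i` = effective-sample shares) to
   known population totals for sex × {age, province, urbanization,
   nationality}, giving the calibrated weights `w_k^(j)` with
   `Ŷ^CAL_{M_j} = Σ w_k y_k`.

On top of the weights it provides the full estimator family — totals,
proportions, change vs. baseline, gender gaps, longitudinal
within-unit differences, gross-change counts, deterioration rates —
and **bias-corrected and accelerated (BCa) bootstrap** confidence
intervals that resample whole unit trajectories within strata. A
synthetic overlapping-panel generator with enumerable ground truth
makes every stage testable without external data.

Intended users: survey statisticians and epidemiologists running
repeated health or social surveys with refreshment samples.

## Worked example

```python
from panelcal import (
    SimulationConfig, NonResponseModel, OutcomeSpec,
    WeightingPipeline, PropensityConfig,
    calibrated_proportion, relative_change,
    gross_change_count, deterioration_rate,
)
from panelcal.simulate import simulate_overlapping_panel, population_margins

config = SimulationConfig(outcome_kind="ordinal",
                          nonresponse=NonResponseModel(coefficients={"x1": -0.8}),
                          seed=12345)
data, frame, truth = simulate_overlapping_panel(config)
margins = population_margins(frame)

pipeline = WeightingPipeline(design=data.design, margins=margins,
                             propensity=PropensityConfig(family="logistic"),
                             seed=12345)

poor = OutcomeSpec("y", positive_classes=frozenset([4, 5]))  # worst 2 of 5
w1, _ = pipeline.cross_sectional(data, 1)
w4, info = pipeline.cross_sectional(data, 4)
p1 = calibrated_proportion(w1, data, poor, 1)
p4 = calibrated_proportion(w4, data, poor, 4)
print(f"poor health share M1: {100*p1.value:.1f}%")
print(f"poor health share M4: {100*p4.value:.1f}%")
print(f"relative change M4 vs M1: {100*relative_change(p4, p1).value:.1f}%")
print(f"alphas at M4: {info['plan'].alphas.round(3).tolist()}")

v, _ = pipeline.longitudinal(data, 4)
worse = gross_change_count(v, data, poor, 4, "increase")
better = gross_change_count(v, data, poor, 4, "decrease")
print(f"worsened M4 vs M3: {100*worse.value/v.total:.1f}%  "
      f"improved: {100*better.value/v.total:.1f}%")
print(f"deterioration rate: {100*deterioration_rate(worse, better).value:.1f}%")
```

Output:

```
poor health share M1: 43.3%
poor health share M4: 43.9%
relative change M4 vs M1: 1.4%
alphas at M4: [0.178, 0.185, 0.281, 0.356]
worsened M4 vs M3: 21.0%  improved: 17.9%
deterioration rate: 17.0%
```

What the numbers mean: the simulated population's poor-health share
at `M_4` is 49.4% while the raw (unweighted) respondent share is only
39.9% — older/high-`x1` units both report worse health and respond
less, so attrition hides half the deterioration. The PSA+calibrated
share of 43.9% removes a substantial part of that gap (residual bias
is expected: panel weights correct each panel's latest transition and
calibration can only use the margin variables). The `alphas` line
shows how the four component samples are pooled at `M_4` in
proportion to their effective sizes. The longitudinal block uses the
calibrated panel-union weights: 21.0% of the population worsened
between `M_3` and `M_4` against 17.9% improving, a deterioration rate
of 17%.

The same pipeline is scriptable from the shell
(`panelcal simulate|weight|calibrate|estimate|ci|run --config cfg.yaml`),
and external microdata can be supplied as long-format CSV with a
margins file; see `panelcal.runner.RunConfig`.

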