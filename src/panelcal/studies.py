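"""Monte-Carlo validation studies for the reweighting pipeline.

These run the package's own machinery against enumerated ground truth
on synthetic studies: Horvitz-Thompson unbiasedness under full
response, bias reduction of the PSA+calibration estimator under MAR
non-response, and coverage of the BCa bootstrap interval for a
calibrated total. Problem sizes are arguments so callers can scale
them; defaults are the sizes used in the package's own validation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .bootstrap import bca_interval, jackknife_acceleration
from .calibrate import rake_arrays
from .dataset import PanelDataset, SampleDesign
from .estimators import OutcomeSpec, calibrated_total
from .pipeline import WeightingPipeline, derive_seed
from .propensity import PropensityConfig
from .simulate import (
    NonResponseModel,
    SimulationConfig,
    draw_new_sample,
    generate_population,
    largest_remainder,
    population_margins,
    simulate_overlapping_panel,
)


def ht_unbiasedness_study(
    N: int = 10_000,
    n: int = 400,
    replicates: int = 2_000,
    seed: int = 0,
    t: int = 1,
) -> dict:
    """Mean of the stratified-design HT total over repeated full-response
    samples, against the enumerated population total.

    Returns the Monte-Carlo mean, the true total, the MC standard
    error of the mean and the z-score (mean - truth) / MC-SE.
    """
    cfg = SimulationConfig(
        N=N, t=t, n_new={1: n},
        nonresponse=NonResponseModel(mechanism="mcar", rate_new=1.0, rate_panel=1.0),
        seed=derive_seed(seed, 31),
    )
    frame = generate_population(cfg)
    truth = float(frame["y1"].sum())
    sizes = frame.groupby("stratum", sort=True).size()
    alloc = largest_remainder(n, sizes.to_dict())
    weight_of = {h: sizes[h] / alloc[h] for h in alloc}
    rng = np.random.default_rng(derive_seed(seed, 32))
    ests = np.empty(replicates)
    # index arrays per stratum: draw within-stratum SRS directly
    pools = {
        h: frame.loc[frame["stratum"] == h, "y1"].to_numpy() for h in alloc
    }
    for r in range(replicates):
        tot = 0.0
        for h, n_h in alloc.items():
            y = pools[h]
            idx = rng.choice(len(y), size=n_h, replace=False)
            tot += weight_of[h] * y[idx].sum()
        ests[r] = tot
    mc_se = float(ests.std(ddof=1) / np.sqrt(replicates))
    return {
        "mean_estimate": float(ests.mean()),
        "true_total": truth,
        "mc_se": mc_se,
        "z": float((ests.mean() - truth) / mc_se),
    }


def mar_bias_study(
    replicates: int = 500,
    seed: int = 0,
    N: int = 5_000,
    n_new: dict | None = None,
    t: int = 3,
    measurement: int | None = None,
) -> dict:
    """Bias of the PSA+calibrated estimator vs. the unadjusted
    respondent estimator under MAR-logistic non-response.

    The outcome loads on the same covariate that drives non-response,
    so the naive respondent mean is biased; the study reports both
    mean biases (relative to the enumerated truth) and their absolute
    ratio. Uses the logistic propensity family.
    """
    n_new = n_new or {1: 300, 2: 250, 3: 300}
    j = measurement or t
    spec = OutcomeSpec("y")
    bias_adj = np.empty(replicates)
    bias_unadj = np.empty(replicates)
    for r in range(replicates):
        cfg = SimulationConfig(
            N=N, t=t, n_new=n_new,
            nonresponse=NonResponseModel(coefficients={"x1": -0.8}),
            seed=derive_seed(seed, 41, r),
        )
        data, frame, truth = simulate_overlapping_panel(cfg)
        margins = population_margins(frame)
        pl = WeightingPipeline(
            design=data.design, margins=margins,
            propensity=PropensityConfig(family="logistic"),
            seed=derive_seed(seed, 42, r),
        )
        w, _ = pl.cross_sectional(data, j)
        est = calibrated_total(w, data, spec, j).value
        resp = data.respondents(j)
        unadj = N * float(resp["y"].mean())
        bias_adj[r] = est - truth["total"][j]
        bias_unadj[r] = unadj - truth["total"][j]
    return {
        "bias_adjusted": float(bias_adj.mean()),
        "bias_unadjusted": float(bias_unadj.mean()),
        "bias_ratio": float(abs(bias_adj.mean()) / abs(bias_unadj.mean())),
        "replicates": replicates,
    }


def coverage_study(
    replicates: int = 400,
    B: int = 400,
    seed: int = 0,
    N: int = 5_000,
    n: int = 150,
    level: float = 0.95,
) -> dict:
    """Coverage of the BCa interval for a calibrated total under a
    full-response stratified design.

    With full response the weighting pipeline reduces to design
    weights followed by raking calibration; that reduced pipeline is
    re-executed for every bootstrap replicate (resampling units within
    strata) and for every leave-one-unit-out jackknife evaluation.
    """
    cfg = SimulationConfig(
        N=N, t=1, n_new={1: n}, mean_shifts=(0.0,),
        nonresponse=NonResponseModel(mechanism="mcar", rate_new=1.0, rate_panel=1.0),
        seed=derive_seed(seed, 51),
    )
    frame = generate_population(cfg)
    truth = float(frame["y1"].sum())
    margins_cols = (("sex", "age_group"), ("sex", "nationality"))
    pop_margins = population_margins(frame, margins_cols)
    sizes = frame.groupby("stratum", sort=True).size()
    alloc = largest_remainder(n, sizes.to_dict())
    weight_of = frame["stratum"].map({h: sizes[h] / alloc[h] for h in alloc})
    frame = frame.assign(_d=weight_of)
    # integer cell codes per margin, aligned with target arrays
    margin_codes = []
    for m in pop_margins:
        cells = list(m.totals)
        code_of = {c: i for i, c in enumerate(cells)}
        labels = m.cell_labels(frame)
        margin_codes.append(
            (labels.map(code_of).to_numpy(dtype=int),
             np.array([m.totals[c] for c in cells]))
        )

    rng = np.random.default_rng(derive_seed(seed, 52))
    covered = 0
    degenerate = 0
    for r in range(replicates):
        sample = draw_new_sample(frame, n, rng)
        pos = sample.index.to_numpy()
        d = frame["_d"].to_numpy()[pos]
        y = frame["y1"].to_numpy()[pos]
        codes = [(c[pos], t_) for c, t_ in margin_codes]
        strata = frame["stratum"].to_numpy()[pos]

        def stat(idx: np.ndarray) -> float:
            sub = [(c[0][idx], c[1]) for c in codes]
            w, _ = rake_arrays(d[idx], sub, bounds=(0.3, 3.0))
            return float(w @ y[idx])

        all_idx = np.arange(len(pos))
        theta = stat(all_idx)
        blocks = [np.flatnonzero(strata == h) for h in np.unique(strata)]
        reps = np.empty(B)
        for b in range(B):
            idx = np.concatenate(
                [rng.choice(blk, size=len(blk), replace=True) for blk in blocks]
            )
            reps[b] = stat(idx)
        loo = np.array(
            [stat(np.delete(all_idx, i)) for i in range(len(all_idx))]
        )
        lo, hi, _, degen = bca_interval(
            theta, reps, jackknife_acceleration(loo), level
        )
        degenerate += degen
        covered += lo <= truth <= hi
    return {
        "coverage": covered / replicates,
        "n_covered": covered,
        "replicates": replicates,
        "B": B,
        "degenerate": degenerate,
    }
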