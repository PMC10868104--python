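"""Bias-corrected and accelerated (BCa) bootstrap for pipeline statistics.

Units are resampled with replacement *within stratum at their
theoretical-sample level* (i.e. within panel x stratum blocks), each
resampled unit carrying its entire response trajectory, so that both
attrition variability and sampling variability propagate into the
replicate distribution. The statistic — typically the whole weighting
pipeline ending in one estimate — is re-executed on every replicate.

The BCa interval adjusts the percentile endpoints with a median-bias
term z0 (from the fraction of replicates below the point estimate) and
an acceleration term a (from the skewness of leave-one-unit-out
jackknife estimates):

    a = sum (tbar - t_i)^3 / (6 * [sum (tbar - t_i)^2]^(3/2)).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd
from scipy.stats import norm

from .dataset import PanelDataset
from .estimators import Estimate


@dataclass
class BootstrapConfig:
    B: int = 1000
    level: float = 0.95
    scheme: str = "stratified_units"  # or "srs_units"
    refit_propensity: bool = False
    jackknife: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.B < 2:
            raise ValueError("need at least 2 bootstrap replicates")
        if not 0 < self.level < 1:
            raise ValueError("level must be in (0, 1)")
        if self.scheme not in ("stratified_units", "srs_units"):
            raise ValueError(f"unknown resampling scheme {self.scheme!r}")


def jackknife_acceleration(loo: np.ndarray) -> float:
    """Acceleration a from leave-one-out estimates; 0 when constant."""
    loo = np.asarray(loo, dtype=float)
    dev = loo.mean() - loo
    ss = float((dev**2).sum())
    if ss == 0:
        return 0.0
    return float((dev**3).sum() / (6.0 * ss**1.5))


def bca_interval(
    theta_hat: float,
    replicates: np.ndarray,
    a: float,
    level: float,
) -> tuple[float, float, float, bool]:
    """BCa endpoints; returns (lo, hi, z0, degenerate_flag)."""
    replicates = np.asarray(replicates, dtype=float)
    B = len(replicates)
    if np.ptp(replicates) == 0:
        return theta_hat, theta_hat, 0.0, True
    frac = np.mean(replicates < theta_hat)
    frac = min(max(frac, 0.5 / B), 1 - 0.5 / B)
    z0 = float(norm.ppf(frac))
    alpha = 1.0 - level
    lo_hi = []
    for q in (alpha / 2.0, 1.0 - alpha / 2.0):
        z = z0 + norm.ppf(q)
        adj = norm.cdf(z0 + z / (1.0 - a * z))
        lo_hi.append(float(np.quantile(replicates, adj)))
    return lo_hi[0], lo_hi[1], z0, False


def _resample_blocks(units: pd.DataFrame, scheme: str) -> list[np.ndarray]:
    """Unit-id pools to resample within (whole-block samples keep sizes)."""
    if scheme == "srs_units":
        return [units.index.to_numpy()]
    grouped = units.groupby(["panel", "stratum"], sort=True)
    return [idx.to_numpy() for _, idx in grouped.groups.items()]


def _replicate(
    data: PanelDataset,
    blocks: list[np.ndarray],
    row_pos: dict,
    rng: np.random.Generator,
) -> PanelDataset:
    sampled: list = []
    for pool in blocks:
        sampled.extend(rng.choice(pool, size=len(pool), replace=True))
    positions = np.concatenate([row_pos[u] for u in sampled])
    counts = np.array([len(row_pos[u]) for u in sampled])
    new_ids = np.repeat(np.arange(len(sampled)), counts)
    df = data.data.iloc[positions].copy()
    df["unit_id"] = new_ids
    # construct without re-validating: the replicate inherits validity
    out = object.__new__(PanelDataset)
    out.data = df.reset_index(drop=True)
    out.covariates = data.covariates
    out.outcomes = data.outcomes
    out.margin_columns = data.margin_columns
    out.design = data.design
    return out


def resample_dataset(
    data: PanelDataset, rng: np.random.Generator, scheme: str = "stratified_units"
) -> PanelDataset:
    """One bootstrap replicate: units drawn with replacement within
    panel x stratum blocks; duplicated units get fresh unit ids so the
    long-format uniqueness contract holds."""
    units = data.unit_table([])
    row_pos = data.data.groupby("unit_id", sort=False).indices
    return _replicate(data, _resample_blocks(units, scheme), row_pos, rng)


def _drop_unit(data: PanelDataset, unit, row_pos) -> PanelDataset:
    keep = np.ones(len(data.data), dtype=bool)
    keep[row_pos[unit]] = False
    out = object.__new__(PanelDataset)
    out.data = data.data.loc[keep]
    out.covariates = data.covariates
    out.outcomes = data.outcomes
    out.margin_columns = data.margin_columns
    out.design = data.design
    return out


def bootstrap_ci(
    statistic: Callable[[PanelDataset], float],
    data: PanelDataset,
    config: BootstrapConfig,
    estimator_name: str = "statistic",
) -> Estimate:
    """BCa confidence interval for ``statistic(data)``.

    The statistic must be deterministic given the dataset (any model
    seeds fixed inside the closure).
    """
    rng = np.random.default_rng(config.seed)
    theta_hat = float(statistic(data))
    units = data.unit_table([])
    row_pos = data.data.groupby("unit_id", sort=False).indices
    blocks = _resample_blocks(units, config.scheme)
    reps = np.empty(config.B)
    for b in range(config.B):
        reps[b] = float(statistic(_replicate(data, blocks, row_pos, rng)))

    if config.jackknife:
        units = list(row_pos)
        loo = np.array([float(statistic(_drop_unit(data, u, row_pos))) for u in units])
        a = jackknife_acceleration(loo)
    else:
        a = 0.0

    lo, hi, z0, degenerate = bca_interval(theta_hat, reps, a, config.level)
    meta = {"z0": z0, "acceleration": a, "B": config.B}
    if degenerate:
        meta["warning"] = "degenerate replicate distribution; zero-width interval"
    return Estimate(
        theta_hat,
        estimator_name,
        ci_low=lo,
        ci_high=hi,
        level=config.level,
        ci_method="bca",
        meta=meta,
    )
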