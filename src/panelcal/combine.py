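"""Convex combination of per-panel and new-sample PSA estimators.

The cross-sectional estimator at measurement j is a convex combination
of the PSA estimators of the component effective samples (panels
1..j-1 plus the new sample at j), with coefficients alpha_i equal to
each component's share of the total effective sample — a rule that
does not depend on the variable being estimated. Scaling each
component's weights by its alpha yields a single weight vector D_k
over the union s_r^{M_j} whose weighted totals reproduce the combined
estimator exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .dataset import WeightVector


@dataclass
class CombinationPlan:
    """Record of one combination step, kept for audit."""

    measurement: int
    components: list  # (panel label, effective size)
    alphas: np.ndarray

    def __post_init__(self) -> None:
        a = np.asarray(self.alphas, dtype=float)
        if (a < 0).any():
            raise ValueError("alpha coefficients must be nonnegative")
        if abs(a.sum() - 1.0) > 1e-12:
            raise ValueError(f"alphas sum to {a.sum()}, expected 1")


def effective_share_alphas(sizes: Sequence[int]) -> np.ndarray:
    """alpha_i = n_r^(i,j) / sum of effective sizes."""
    sizes = np.asarray(sizes, dtype=float)
    if len(sizes) == 0:
        raise ValueError("need at least one component")
    if (sizes < 0).any() or sizes.sum() <= 0:
        raise ValueError("effective sizes must be nonnegative with positive sum")
    return sizes / sizes.sum()


def combine_weights(
    components: Sequence[WeightVector],
    alphas: Sequence[float] | None = None,
) -> tuple[WeightVector, CombinationPlan]:
    """Scale each component's weights by its alpha and concatenate.

    Components must cover pairwise-disjoint unit sets. If ``alphas``
    is omitted, the effective-share rule is applied to the component
    sizes.
    """
    if not components:
        raise ValueError("need at least one component weight vector")
    j = components[0].measurement
    if any(c.measurement != j for c in components):
        raise ValueError("all components must belong to the same measurement")
    sizes = [len(c) for c in components]
    a = (
        effective_share_alphas(sizes)
        if alphas is None
        else np.asarray(alphas, dtype=float)
    )
    all_ids = pd.concat([c.weights for c in components]).index
    if all_ids.has_duplicates:
        dup = all_ids[all_ids.duplicated()].unique()[:5].tolist()
        raise ValueError(f"component samples overlap; duplicate unit ids {dup}")
    scaled = pd.concat(
        [c.weights * ai for c, ai in zip(components, a)]
    )
    plan = CombinationPlan(
        measurement=j,
        components=[(c.panel, n) for c, n in zip(components, sizes)],
        alphas=a,
    )
    return WeightVector(scaled, stage="combined", measurement=j), plan
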