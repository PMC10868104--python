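"""Design weights and the response-rate adjustment.

The design weight of a unit in a stratified SRS is the inverse of its
inclusion probability, N_h / n_h^(j); under exactly proportional
allocation it reduces to N / n^(j) for every unit (self-weighting).
The first, naive correction for total non-response divides the design
weight by the observed response rate r = n_r / n, computed either
overall or within each stratum (the response-homogeneity classes).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .dataset import PanelDataset, SampleDesign, WeightVector


class EstimationError(ValueError):
    """Raised when a weighting stage cannot be computed."""


def design_weight(
    design: SampleDesign, data: PanelDataset, j: int
) -> WeightVector:
    """Per-stratum design weights N_h / n_h^(j) for the new sample s^(j).

    Covers every theoretical-sample unit (respondent or not).
    """
    sample = data.new_sample(j)
    n_h = design.n_new[j]
    w = np.empty(len(sample))
    for h, grp in sample.groupby("stratum", sort=True):
        n = n_h.get(h, 0)
        if n == 0:
            raise EstimationError(f"stratum {h!r} has sampled units but n_h=0")
        w[sample["stratum"].to_numpy() == h] = design.strata_sizes[h] / n
    return WeightVector(
        pd.Series(w, index=sample["unit_id"].to_numpy()),
        stage="design",
        measurement=j,
        panel=j,
    )


def response_rate_adjust(
    weights: WeightVector,
    data: PanelDataset,
    j: int,
    scope: str = "per_stratum",
) -> WeightVector:
    """Divide respondent weights by the response rate r = n_r / n.

    ``scope`` is ``"per_stratum"`` (a rate per response-homogeneity
    class, the default) or ``"overall"``. Nonrespondents are dropped
    from the returned vector.
    """
    if scope not in ("per_stratum", "overall"):
        raise ValueError(f"unknown scope {scope!r}")
    sample = data.rows(j, panel=weights.panel if weights.panel != "new" else None)
    sample = sample.set_index("unit_id").loc[weights.weights.index]
    delta = sample["delta"].to_numpy()
    if scope == "overall":
        n, n_r = len(sample), int(delta.sum())
        if n_r == 0:
            raise EstimationError(f"response rate is 0 at measurement {j}")
        r = pd.Series(n_r / n, index=sample.index)
    else:
        grp = sample.groupby("stratum")["delta"]
        rates = grp.mean()
        dead = rates[rates == 0]
        if len(dead):
            raise EstimationError(
                f"response rate is 0 in class(es) {list(dead.index)} at measurement {j}"
            )
        r = sample["stratum"].map(rates)
    adj = weights.weights / r.to_numpy()
    return WeightVector(
        adj[delta == 1],
        stage="response_rate",
        measurement=j,
        panel=weights.panel,
    )


def naive_total(
    weights: WeightVector, data: PanelDataset, outcome: str, j: int
) -> float:
    """Weighted total of one outcome over the respondents covered by
    ``weights`` at measurement j."""
    resp = data.respondents(j)
    resp = resp.set_index("unit_id")
    ids = weights.weights.index.intersection(resp.index)
    y = resp.loc[ids, outcome].to_numpy(dtype=float)
    return float(np.dot(weights.weights.loc[ids].to_numpy(), y))
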