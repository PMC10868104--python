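"""Point estimators built on calibrated weight vectors.

Cross-sectional (from the calibrated weights w of measurement j):
totals, class proportions, absolute/relative change vs. measurement 1
and absolute/relative gender gaps. Longitudinal (from calibrated
weights v over the union of panel effective samples at j): weighted
within-unit differences, gross-change counts over a change class A in
{increase, decrease, same}, the deterioration/improvement rate, and
gender gaps of the gross-change counts.

Sign convention for gender gaps: positive means the women's value
exceeds the men's; interpretation (favorable/unfavorable) depends on
the outcome's polarity and is left to the caller.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .dataset import PanelDataset, WeightVector

CHANGE_CLASSES = ("increase", "decrease", "same")


class UndefinedRatioError(ZeroDivisionError):
    """A ratio estimator's denominator is zero."""


@dataclass
class OutcomeSpec:
    """What to estimate: outcome column, optional dichotomization
    (category set mapped to 1), the sex column and optional domain."""

    outcome: str
    positive_classes: frozenset | None = None  # -> indicator outcome
    sex_column: str = "sex"
    women_label: str = "W"
    men_label: str = "M"
    domain: Mapping[str, Sequence] | None = None  # column -> allowed values
    same_epsilon: float = 0.0  # |diff| <= eps counts as "same"

    def values(self, rows: pd.DataFrame, column: str | None = None) -> np.ndarray:
        y = rows[column or self.outcome]
        if self.positive_classes is not None:
            return y.isin(self.positive_classes).to_numpy(dtype=float)
        return y.to_numpy(dtype=float)

    def domain_mask(self, rows: pd.DataFrame) -> np.ndarray:
        mask = np.ones(len(rows), dtype=bool)
        if self.domain:
            for col, allowed in self.domain.items():
                mask &= rows[col].isin(list(allowed)).to_numpy()
        return mask


@dataclass
class Estimate:
    """A point estimate, optionally with a confidence interval."""

    value: float
    estimator: str
    measurement: object = None
    ci_low: float | None = None
    ci_high: float | None = None
    level: float | None = None
    ci_method: str | None = None
    n_effective: int | None = None
    meta: dict = field(default_factory=dict)

    def __float__(self) -> float:
        return float(self.value)

    def to_row(self) -> dict:
        return {
            "estimator": self.estimator,
            "measurement": str(self.measurement),
            "value": self.value,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "level": self.level,
            "n_effective": self.n_effective,
        }


def _aligned_rows(w: WeightVector, data: PanelDataset, j: int) -> pd.DataFrame:
    resp = data.respondents(j).set_index("unit_id")
    return resp.loc[w.weights.index]


# --------------------------------------------------------------------
# cross-sectional
# --------------------------------------------------------------------

def calibrated_total(
    w: WeightVector, data: PanelDataset, spec: OutcomeSpec, j: int
) -> Estimate:
    """Weighted total sum_k w_k y_k over the effective sample of M_j."""
    rows = _aligned_rows(w, data, j)
    mask = spec.domain_mask(rows)
    y = spec.values(rows) * mask
    val = float(np.dot(w.weights.to_numpy(), y))
    return Estimate(val, "total", j, n_effective=int(mask.sum()))


def calibrated_proportion(
    w: WeightVector, data: PanelDataset, spec: OutcomeSpec, j: int
) -> Estimate:
    """Weighted share of the positive class within the domain."""
    rows = _aligned_rows(w, data, j)
    mask = spec.domain_mask(rows)
    wts = w.weights.to_numpy() * mask
    denom = float(wts.sum())
    if denom == 0:
        raise UndefinedRatioError("empty domain: proportion undefined")
    y = spec.values(rows)
    val = float(np.dot(wts, y) / denom)
    return Estimate(val, "proportion", j, n_effective=int(mask.sum()))


def absolute_change(est_j: Estimate, est_1: Estimate) -> Estimate:
    """Difference of two calibrated estimates (measurement j vs. 1)."""
    return Estimate(
        est_j.value - est_1.value,
        "abs_change",
        (est_j.measurement, est_1.measurement),
    )


def relative_change(est_j: Estimate, est_1: Estimate) -> Estimate:
    """Absolute change divided by the baseline estimate."""
    if est_1.value == 0:
        raise UndefinedRatioError("baseline estimate is 0: relative change undefined")
    return Estimate(
        (est_j.value - est_1.value) / est_1.value,
        "rel_change",
        (est_j.measurement, est_1.measurement),
    )


def _by_sex(
    w: WeightVector, data: PanelDataset, spec: OutcomeSpec, j: int,
    statistic: str = "total",
) -> tuple[float, float]:
    fn = calibrated_total if statistic == "total" else calibrated_proportion
    women = OutcomeSpec(
        spec.outcome, spec.positive_classes, spec.sex_column,
        spec.women_label, spec.men_label,
        {**(spec.domain or {}), spec.sex_column: [spec.women_label]},
        spec.same_epsilon,
    )
    men = OutcomeSpec(
        spec.outcome, spec.positive_classes, spec.sex_column,
        spec.women_label, spec.men_label,
        {**(spec.domain or {}), spec.sex_column: [spec.men_label]},
        spec.same_epsilon,
    )
    return fn(w, data, women, j).value, fn(w, data, men, j).value


def gender_gap_abs(
    w: WeightVector, data: PanelDataset, spec: OutcomeSpec, j: int,
    statistic: str = "total",
) -> Estimate:
    """Women's estimate minus men's estimate at measurement j."""
    yw, ym = _by_sex(w, data, spec, j, statistic)
    return Estimate(yw - ym, "gender_gap_abs", j, meta={"women": yw, "men": ym})


def gender_gap_rel(
    w: WeightVector, data: PanelDataset, spec: OutcomeSpec, j: int,
    statistic: str = "total",
) -> Estimate:
    """Absolute gender gap divided by the men's estimate."""
    yw, ym = _by_sex(w, data, spec, j, statistic)
    if ym == 0:
        raise UndefinedRatioError("men's estimate is 0: relative gender gap undefined")
    return Estimate((yw - ym) / ym, "gender_gap_rel", j, meta={"women": yw, "men": ym})


# --------------------------------------------------------------------
# longitudinal
# --------------------------------------------------------------------

def _longitudinal_frame(
    v: WeightVector, data: PanelDataset, spec: OutcomeSpec, j: int
) -> pd.DataFrame:
    """Rows of the longitudinal sample with y at j and j-1 and weights."""
    wide = data.outcome_wide(spec.outcome)
    ids = v.weights.index
    rows = data.respondents(j).set_index("unit_id").loc[ids]
    out = pd.DataFrame(index=ids)
    if j - 1 not in wide.columns or wide.loc[ids, [j - 1, j]].isna().any().any():
        raise ValueError(
            "longitudinal sample contains units without both outcomes observed"
        )
    if spec.positive_classes is not None:
        out["y_j"] = wide.loc[ids, j].isin(spec.positive_classes).astype(float)
        out["y_prev"] = wide.loc[ids, j - 1].isin(spec.positive_classes).astype(float)
    else:
        out["y_j"] = wide.loc[ids, j].to_numpy(dtype=float)
        out["y_prev"] = wide.loc[ids, j - 1].to_numpy(dtype=float)
    out["v"] = v.weights
    out[spec.sex_column] = rows[spec.sex_column]
    for col in (spec.domain or {}):
        if col not in out.columns:
            out[col] = rows[col]
    return out


def longitudinal_difference(
    v: WeightVector, data: PanelDataset, spec: OutcomeSpec, j: int
) -> Estimate:
    """sum_k v_k (y_k^(j) - y_k^(j-1)) over the panel union at j."""
    fr = _longitudinal_frame(v, data, spec, j)
    mask = spec.domain_mask(fr)
    val = float(np.dot(fr["v"].to_numpy() * mask, (fr["y_j"] - fr["y_prev"]).to_numpy()))
    return Estimate(val, "long_diff", (j, j - 1), n_effective=int(mask.sum()))


def _class_indicator(diff: np.ndarray, a: str, eps: float) -> np.ndarray:
    if a == "increase":
        return (diff > eps).astype(float)
    if a == "decrease":
        return (diff < -eps).astype(float)
    if a == "same":
        return (np.abs(diff) <= eps).astype(float)
    raise ValueError(f"unknown change class {a!r}; expected one of {CHANGE_CLASSES}")


def gross_change_count(
    v: WeightVector, data: PanelDataset, spec: OutcomeSpec, j: int, a: str
) -> Estimate:
    """Estimated count of population units whose outcome moved into
    class ``a`` (increase / decrease / same) between j-1 and j."""
    fr = _longitudinal_frame(v, data, spec, j)
    mask = spec.domain_mask(fr)
    diff = (fr["y_j"] - fr["y_prev"]).to_numpy()
    ind = _class_indicator(diff, a, spec.same_epsilon)
    val = float(np.dot(fr["v"].to_numpy() * mask, ind))
    return Estimate(val, f"gross_{a}", (j, j - 1), n_effective=int(mask.sum()))


def deterioration_rate(decrease: Estimate, increase: Estimate) -> Estimate:
    """(decrease - increase) / increase: relative excess of units
    moving down over units moving up."""
    if increase.value == 0:
        raise UndefinedRatioError("increase count is 0: rate undefined")
    return Estimate(
        (decrease.value - increase.value) / increase.value,
        "rate",
        decrease.measurement,
    )


def longitudinal_gender_gap(
    v: WeightVector, data: PanelDataset, spec: OutcomeSpec, j: int, a: str
) -> tuple[Estimate, Estimate]:
    """Absolute and relative gender gaps of the class-``a`` count."""
    fr = _longitudinal_frame(v, data, spec, j)
    mask = spec.domain_mask(fr)
    diff = (fr["y_j"] - fr["y_prev"]).to_numpy()
    ind = _class_indicator(diff, a, spec.same_epsilon) * mask
    wv = fr["v"].to_numpy()
    is_w = (fr[spec.sex_column] == spec.women_label).to_numpy()
    cnt_w = float(np.dot(wv * is_w, ind))
    cnt_m = float(np.dot(wv * ~is_w, ind))
    abs_gap = Estimate(
        cnt_w - cnt_m, f"long_gg_abs_{a}", (j, j - 1),
        meta={"women": cnt_w, "men": cnt_m},
    )
    if cnt_m == 0:
        raise UndefinedRatioError("men's count is 0: relative gender gap undefined")
    rel_gap = Estimate((cnt_w - cnt_m) / cnt_m, f"long_gg_rel_{a}", (j, j - 1))
    return abs_gap, rel_gap
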