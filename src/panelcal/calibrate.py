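"""Calibration of survey weights to known population margin totals.

Given base weights D_k (from the reweighting/combination phase) and
population totals X*_c per cell of one or more calibration margins
(e.g. sex x age group), calibration finds weights w_k as close as
possible to D_k under a distance G while satisfying

    sum_{k in cell c} w_k = X*_c          for every cell of every margin.

Two distances are supported:

* ``raking`` — multiplicative iterative proportional fitting (IPF)
  over the margins, optionally *truncated*: after each full cycle the
  per-unit adjustment ratio w_k / D_k is clamped to [L, U] and the
  residual error is redistributed over the unclamped units by further
  cycles.
* ``linear`` — the generalized regression (GREG) adjustment
  w_k = D_k (1 + x_k' lambda), solved in closed form; no truncation.

Margins are treated as separate cross-classifications, not one full
interaction table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .dataset import WeightVector


class CalibrationError(ValueError):
    """Infeasible calibration problem (e.g. empty cell with positive target)."""


@dataclass
class MarginTotals:
    """Population totals for the cells of one calibration margin.

    ``columns`` names the unit attributes whose cross-classification
    defines the cells; ``totals`` maps each cell (a tuple of attribute
    values) to its population total X*.
    """

    name: str
    columns: tuple[str, ...]
    totals: Mapping[tuple, float]

    def __post_init__(self) -> None:
        self.columns = tuple(self.columns)
        norm = {}
        for cell, total in self.totals.items():
            if not isinstance(cell, tuple):
                cell = (cell,)
            if total <= 0:
                raise CalibrationError(
                    f"margin {self.name!r}: cell {cell} has non-positive total {total}"
                )
            norm[cell] = float(total)
        self.totals = norm

    @property
    def population_total(self) -> float:
        return float(sum(self.totals.values()))

    def cell_labels(self, memberships: pd.DataFrame) -> pd.Series:
        cols = [memberships[c] for c in self.columns]
        return pd.Series(list(zip(*[c.to_numpy() for c in cols])), index=memberships.index)


@dataclass
class CalibrationSpec:
    """Distance, truncation and stopping settings for one calibration."""

    margins: Sequence[MarginTotals]
    distance: str = "raking"  # or "linear"
    bounds: tuple[float, float] | None = (0.3, 3.0)
    tolerance: float = 1e-8
    max_iterations: int = 500

    def __post_init__(self) -> None:
        if self.distance not in ("raking", "linear"):
            raise ValueError(f"unknown distance {self.distance!r}")
        if self.bounds is not None:
            L, U = self.bounds
            if not 0 < L < 1 < U:
                raise ValueError("truncation bounds must satisfy 0 < L < 1 < U")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")


def _index_margins(
    memberships: pd.DataFrame, margins: Sequence[MarginTotals]
) -> list[tuple[np.ndarray, np.ndarray, MarginTotals]]:
    """Precompute (per-unit cell code, target array) for each margin."""
    out = []
    for m in margins:
        labels = m.cell_labels(memberships)
        cells = list(m.totals)
        code_of = {c: i for i, c in enumerate(cells)}
        unknown = [l for l in labels.unique() if l not in code_of]
        if unknown:
            raise CalibrationError(
                f"margin {m.name!r}: sample cells {unknown[:5]} have no population total"
            )
        codes = labels.map(code_of).to_numpy(dtype=int)
        targets = np.array([m.totals[c] for c in cells])
        present = np.bincount(codes, minlength=len(cells)) > 0
        empty = [cells[i] for i in np.nonzero(~present)[0]]
        if empty:
            raise CalibrationError(
                f"margin {m.name!r}: cells {empty[:5]} have positive targets "
                "but no sample units"
            )
        out.append((codes, targets, m))
    return out


def _max_rel_error(w: np.ndarray, margins) -> float:
    """Max relative cell error over margins, ignoring cells with no
    sample units (the high-level calibrator rejects those upfront)."""
    err = 0.0
    for codes, targets, *_ in margins:
        achieved = np.bincount(codes, weights=w, minlength=len(targets))
        present = np.bincount(codes, minlength=len(targets)) > 0
        if present.any():
            gap = np.abs(achieved[present] / targets[present] - 1.0)
            err = max(err, float(gap.max()))
    return err


def rake_arrays(
    d: np.ndarray,
    margins: Sequence[tuple[np.ndarray, np.ndarray]],
    bounds: tuple[float, float] | None = (0.3, 3.0),
    tolerance: float = 1e-8,
    max_iterations: int = 500,
) -> tuple[np.ndarray, dict]:
    """Truncated raking on pre-indexed cells (the IPF core).

    ``margins`` is a list of (per-unit integer cell code, target total
    per cell) pairs. After each full cycle over the margins the
    adjustment ratio w/d is clamped to ``bounds``; cycling continues
    until every margin's maximum relative error drops below
    ``tolerance``. Cells with no sample units are skipped (the
    high-level calibrator rejects them upfront; this core tolerates
    them so bootstrap replicates with empty rare cells remain usable).
    Returns (weights, diagnostics).
    """
    d = np.asarray(d, dtype=float)
    w = d.copy()
    # cells present in the sample are fixed by the codes, not the weights
    indexed = []
    for codes, targets in margins:
        present = np.bincount(codes, minlength=len(targets)) > 0
        indexed.append((codes, np.asarray(targets, dtype=float), present))

    def max_err(wv: np.ndarray) -> float:
        e = 0.0
        for codes, targets, present in indexed:
            achieved = np.bincount(codes, weights=wv, minlength=len(targets))
            gap = np.abs(achieved[present] / targets[present] - 1.0)
            if gap.size:
                e = max(e, float(gap.max()))
        return e

    err = max_err(w)
    it = 0
    if err >= tolerance:
        lo_w = hi_w = None
        if bounds is not None:
            L, U = bounds
            lo_w, hi_w = L * d, U * d
        for it in range(1, max_iterations + 1):
            for codes, targets, present in indexed:
                achieved = np.bincount(codes, weights=w, minlength=len(targets))
                factor = np.ones_like(achieved)
                factor[present] = targets[present] / achieved[present]
                w *= factor[codes]
            if bounds is not None:
                np.clip(w, lo_w, hi_w, out=w)
            err = max_err(w)
            if err < tolerance:
                break
    converged = err < tolerance
    g = w / d
    n_trunc = 0
    if bounds is not None:
        L, U = bounds
        n_trunc = int(((g <= L * (1 + 1e-12)) | (g >= U * (1 - 1e-12))).sum())
    diag = {
        "iterations": it,
        "max_rel_error": err,
        "converged": bool(converged),
        "n_truncated": n_trunc,
        "ratio_min": float(g.min()),
        "ratio_max": float(g.max()),
        "warning": None if converged else "calibration did not converge",
    }
    return w, diag


class RakingCalibrator(BaseEstimator):
    """Sklearn-style calibration transformer over margin memberships.

    ``fit(X, d)`` takes the unit-level membership table ``X`` (one
    column per attribute referenced by the margins) and base weights
    ``d``, and computes the calibrated weights.

    Attributes (after fit)
    ----------------------
    weights_ : calibrated weights, aligned with the rows of ``X``.
    g_ : per-unit adjustment ratios weights_ / d.
    diagnostics_ : dict with iterations, max margin relative error,
        convergence flag, truncated-unit count and ratio summary.
    """

    def __init__(
        self,
        margins: Sequence[MarginTotals] = (),
        distance: str = "raking",
        bounds: tuple[float, float] | None = (0.3, 3.0),
        tolerance: float = 1e-8,
        max_iterations: int = 500,
    ):
        self.margins = margins
        self.distance = distance
        self.bounds = bounds
        self.tolerance = tolerance
        self.max_iterations = max_iterations

    def _spec(self) -> CalibrationSpec:
        return CalibrationSpec(
            margins=self.margins,
            distance=self.distance,
            bounds=self.bounds,
            tolerance=self.tolerance,
            max_iterations=self.max_iterations,
        )

    def fit(self, X: pd.DataFrame, d):
        spec = self._spec()
        d = np.asarray(d, dtype=float)
        if (d <= 0).any():
            raise CalibrationError("base weights must be strictly positive")
        indexed = _index_margins(pd.DataFrame(X), spec.margins)

        if spec.distance == "linear":
            w, diag = self._greg(d, indexed, spec)
        else:
            w, diag = self._raking(d, indexed, spec)

        self.weights_ = w
        self.g_ = w / d
        self.diagnostics_ = diag
        return self

    def fit_transform(self, X, d) -> np.ndarray:
        return self.fit(X, d).weights_

    # -- solvers ------------------------------------------------------

    def _raking(self, d, indexed, spec):
        pairs = [(codes, targets) for codes, targets, _ in indexed]
        return rake_arrays(
            d, pairs,
            bounds=spec.bounds,
            tolerance=spec.tolerance,
            max_iterations=spec.max_iterations,
        )

    def _greg(self, d, indexed, spec):
        # dummy matrix over all margin cells; normal equations via lstsq
        # (cell indicators are collinear across margins, lstsq handles it)
        blocks = []
        targets = []
        for codes, tg, _ in indexed:
            Xm = np.zeros((len(d), len(tg)))
            Xm[np.arange(len(d)), codes] = 1.0
            blocks.append(Xm)
            targets.append(tg)
        X = np.hstack(blocks)
        t = np.concatenate(targets)
        A = X.T @ (d[:, None] * X)
        b = t - X.T @ d
        lam, *_ = np.linalg.lstsq(A, b, rcond=None)
        w = d * (1.0 + X @ lam)
        err = _max_rel_error(w, indexed)
        diag = {
            "iterations": 1,
            "max_rel_error": err,
            "converged": bool(err < spec.tolerance),
            "n_truncated": 0,
            "ratio_min": float((w / d).min()),
            "ratio_max": float((w / d).max()),
            "warning": None if err < spec.tolerance else "GREG system inconsistent",
        }
        return w, diag


def calibrate(
    weights: WeightVector,
    memberships: pd.DataFrame,
    spec: CalibrationSpec,
) -> tuple[WeightVector, dict]:
    """Calibrate a weight vector to the margins in ``spec``.

    ``memberships`` must be indexed by unit_id and cover every unit of
    the weight vector.
    """
    mem = memberships.loc[weights.weights.index]
    cal = RakingCalibrator(
        margins=spec.margins,
        distance=spec.distance,
        bounds=spec.bounds,
        tolerance=spec.tolerance,
        max_iterations=spec.max_iterations,
    )
    w = cal.fit_transform(mem, weights.weights.to_numpy())
    out = WeightVector(
        pd.Series(w, index=weights.weights.index),
        stage="calibrated",
        measurement=weights.measurement,
        panel=weights.panel,
    )
    return out, cal.diagnostics_


def margin_report(
    weights: pd.Series | WeightVector,
    memberships: pd.DataFrame,
    margins: Sequence[MarginTotals],
) -> pd.DataFrame:
    """Achieved total and relative error per margin cell."""
    if isinstance(weights, WeightVector):
        weights = weights.weights
    mem = memberships.loc[weights.index]
    rows = []
    for m in margins:
        labels = m.cell_labels(mem)
        achieved = weights.groupby(labels.to_numpy()).sum()
        for cell, target in m.totals.items():
            got = float(achieved.get(cell, 0.0))
            rows.append(
                {
                    "margin": m.name,
                    "cell": "|".join(map(str, cell)),
                    "target": target,
                    "achieved": got,
                    "rel_error": got / target - 1.0,
                }
            )
    return pd.DataFrame(rows, columns=["margin", "cell", "target", "achieved", "rel_error"])
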