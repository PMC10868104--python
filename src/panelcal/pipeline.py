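"""The end-to-end reweighting pipeline.

Order of stages at each measurement j:

1. design weights for the new theoretical sample (stratified SRS);
2. propensity model per component: the new sample s^(j) (trained on
   all theoretical-sample units with frame covariates) and each live
   panel i < j (trained on the survivors s_r^(i,j-1), optionally with
   their previously observed outcomes);
3. PSA weights per component;
4. convex combination with effective-share alphas -> D_k^(j);
5. truncated raking calibration to the population margins -> w_k^(j).

Longitudinal weights v_k^(j,j-1) take the panel components only
(excluding the fresh sample at j), combine them with effective-share
alphas and calibrate with the same margins.

A single global seed fans out into per-stage seeds through a fixed
derivation so each stage is independently reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .calibrate import CalibrationSpec, MarginTotals, calibrate, margin_report
from .combine import CombinationPlan, combine_weights
from .dataset import PanelDataset, SampleDesign, WeightVector
from .propensity import (
    DegenerateFitError,
    PropensityConfig,
    PropensityFit,
    fit_propensity,
    mcar_fallback_fit,
    panel_training_rows,
    psa_weights_new,
    psa_weights_panel,
)
from .weights import design_weight, response_rate_adjust


def derive_seed(base: int, *parts: int) -> int:
    """Deterministic sub-seed below 2**31 from a global seed and a
    stage key."""
    ss = np.random.SeedSequence([int(base)] + [int(p) & 0x7FFFFFFF for p in parts])
    return int(ss.generate_state(1)[0] % 2**31)


# stage tags for seed derivation
_TAG_NEW, _TAG_PANEL, _TAG_BOOT = 1, 2, 3


def _predicted_fit(
    orig: PropensityFit, rows: pd.DataFrame, cols: Sequence[str]
) -> PropensityFit:
    """Score new rows with an already-fitted propensity model (used by
    bootstrap replicates when refitting is disabled)."""
    ids = rows["unit_id"].to_numpy()
    if orig.model is None:
        corrected = pd.Series(np.full(len(ids), orig.p), index=ids)
        raw = corrected.copy()
    else:
        scores = orig.model.corrected_propensity(rows[list(cols)])
        corrected = pd.Series(scores, index=ids)
        lo, hi = orig.model.clip
        raw = pd.Series(
            np.clip(orig.model.predict_proba(rows[list(cols)])[:, 1], lo, hi),
            index=ids,
        )
    return PropensityFit(
        raw=raw, corrected=corrected, p=orig.p,
        best_params=orig.best_params, cv_loss=orig.cv_loss, seed=orig.seed,
        model=orig.model,
    )


@dataclass
class WeightingPipeline:
    """Reusable weighting machine for one study design.

    Parameters
    ----------
    design : SampleDesign
    margins : population margin totals for calibration.
    propensity : PropensityConfig (family, search budget, clipping).
    calibration : distance/truncation/stopping settings; its
        ``margins`` field is overridden by ``margins``.
    seed : global seed fanned out to per-stage seeds.
    """

    design: SampleDesign
    margins: Sequence[MarginTotals]
    propensity: PropensityConfig = field(default_factory=PropensityConfig)
    calibration: CalibrationSpec | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.calibration is None:
            self.calibration = CalibrationSpec(margins=self.margins)
        else:
            self.calibration = CalibrationSpec(
                margins=self.margins,
                distance=self.calibration.distance,
                bounds=self.calibration.bounds,
                tolerance=self.calibration.tolerance,
                max_iterations=self.calibration.max_iterations,
            )

    # -- propensity fits ---------------------------------------------

    def _fit_new(self, data: PanelDataset, j: int) -> PropensityFit:
        sample = data.new_sample(j)
        rows = sample[["unit_id"] + list(data.covariates)]
        cfg = PropensityConfig(
            family=self.propensity.family,
            n_trials=self.propensity.n_trials,
            cv_folds=self.propensity.cv_folds,
            clip=self.propensity.clip,
            include_prior_outcomes=self.propensity.include_prior_outcomes,
            seed=derive_seed(self.seed, _TAG_NEW, j),
            search_space=self.propensity.search_space,
        )
        try:
            return fit_propensity(rows, sample["delta"].to_numpy(), cfg)
        except DegenerateFitError:
            return mcar_fallback_fit(rows, sample["delta"].to_numpy(), seed=cfg.seed)

    def _fit_panel(self, data: PanelDataset, i: int, j: int) -> PropensityFit:
        rows, delta = panel_training_rows(
            data, i, j, self.propensity.include_prior_outcomes
        )
        cfg = PropensityConfig(
            family=self.propensity.family,
            n_trials=self.propensity.n_trials,
            cv_folds=self.propensity.cv_folds,
            clip=self.propensity.clip,
            include_prior_outcomes=self.propensity.include_prior_outcomes,
            seed=derive_seed(self.seed, _TAG_PANEL, i, j),
            search_space=self.propensity.search_space,
        )
        try:
            return fit_propensity(rows, delta, cfg)
        except DegenerateFitError:
            return mcar_fallback_fit(rows, delta, seed=cfg.seed)

    def propensity_fits(
        self, data: PanelDataset, j: int
    ) -> dict[tuple, PropensityFit]:
        """All component propensity fits for measurement j."""
        fits: dict[tuple, PropensityFit] = {}
        for i in data.panels_at(j):
            if i == j:
                fits[("new", j)] = self._fit_new(data, j)
            else:
                fits[(i, j)] = self._fit_panel(data, i, j)
        return fits

    def _component_fits(
        self,
        data: PanelDataset,
        j: int,
        prefit: Mapping[tuple, PropensityFit] | None,
    ) -> dict[tuple, PropensityFit]:
        if prefit is None:
            return self.propensity_fits(data, j)
        fits = {}
        for i in data.panels_at(j):
            key = ("new", j) if i == j else (i, j)
            orig = prefit[key]
            if i == j:
                rows = data.new_sample(j)[["unit_id"] + list(data.covariates)]
                cols = list(data.covariates)
            else:
                rows, _ = panel_training_rows(
                    data, i, j, self.propensity.include_prior_outcomes
                )
                cols = [c for c in rows.columns if c != "unit_id"]
            fits[key] = _predicted_fit(orig, rows, cols)
        return fits

    # -- weight vectors ----------------------------------------------

    def psa_components(
        self,
        data: PanelDataset,
        j: int,
        prefit: Mapping[tuple, PropensityFit] | None = None,
        include_new: bool = True,
    ) -> tuple[list[WeightVector], dict[tuple, PropensityFit]]:
        fits = self._component_fits(data, j, prefit)
        comps = []
        for i in data.panels_at(j):
            if i == j:
                if include_new:
                    comps.append(psa_weights_new(self.design, data, fits[("new", j)], j))
            else:
                comps.append(psa_weights_panel(self.design, data, fits[(i, j)], i, j))
        return comps, fits

    def cross_sectional(
        self,
        data: PanelDataset,
        j: int,
        prefit: Mapping[tuple, PropensityFit] | None = None,
    ) -> tuple[WeightVector, dict]:
        """Calibrated cross-sectional weights w_k^(j) plus diagnostics."""
        comps, fits = self.psa_components(data, j, prefit)
        combined, plan = combine_weights(comps)
        mem = data.unit_table(data.margin_columns)
        w, diag = calibrate(combined, mem, self.calibration)
        info = {
            "plan": plan,
            "calibration": diag,
            "fits": fits,
            "combined": combined,
            "components": comps,
        }
        return w, info

    def longitudinal(
        self,
        data: PanelDataset,
        j: int,
        prefit: Mapping[tuple, PropensityFit] | None = None,
    ) -> tuple[WeightVector, dict]:
        """Calibrated longitudinal weights v_k^(j,j-1) over the union
        of panel effective samples at j (fresh sample excluded)."""
        if j < 2:
            raise ValueError("longitudinal weights need j >= 2")
        comps, fits = self.psa_components(data, j, prefit, include_new=False)
        if not comps:
            raise ValueError(f"no panel components at measurement {j}")
        combined, plan = combine_weights(comps)
        mem = data.unit_table(data.margin_columns)
        v, diag = calibrate(combined, mem, self.calibration)
        return v, {"plan": plan, "calibration": diag, "fits": fits}

    # -- baseline (no-model) weights, for comparison ------------------

    def response_rate_weights(
        self, data: PanelDataset, j: int, scope: str = "per_stratum"
    ) -> WeightVector:
        """Response-rate-adjusted design weights for the new sample."""
        d = design_weight(self.design, data, j)
        return response_rate_adjust(d, data, j, scope=scope)
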