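"""Run-configuration handling and the chained pipeline runner.

A run is described by a YAML mapping (see ``RunConfig.from_dict``):
where the microdata come from (a CSV path, or the bundled simulator),
the margin totals, the propensity/calibration settings, the estimator
requests and the bootstrap block. ``run()`` executes

    design -> response rate -> PSA -> combine -> calibrate
           -> estimators -> bootstrap

in order, persisting every stage's weight vector, diagnostics and the
estimate tables under the configured output directory.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import io as pio
from .bootstrap import BootstrapConfig, bootstrap_ci
from .calibrate import CalibrationSpec, MarginTotals, margin_report
from .dataset import PanelDataset, SampleDesign, WeightVector
from .estimators import (
    CHANGE_CLASSES,
    Estimate,
    OutcomeSpec,
    absolute_change,
    calibrated_proportion,
    calibrated_total,
    deterioration_rate,
    gender_gap_abs,
    gender_gap_rel,
    gross_change_count,
    longitudinal_difference,
    longitudinal_gender_gap,
    relative_change,
)
from .pipeline import WeightingPipeline, derive_seed, _TAG_BOOT
from .propensity import PropensityConfig
from .simulate import (
    DEFAULT_MAR_COEFFICIENTS,
    DEFAULT_MARGINS,
    NonResponseModel,
    SimulationConfig,
    population_margins,
    simulate_overlapping_panel,
)

log = logging.getLogger("panelcal")

CROSS_SECTIONAL = {
    "total", "proportion", "abs_change", "rel_change",
    "gender_gap_abs", "gender_gap_rel",
}
LONGITUDINAL = {"long_diff", "gross_change", "rate", "long_gender_gap"}


@dataclass
class RunConfig:
    """Structured run configuration; see ``from_dict`` for the schema."""

    seed: int = 0
    output_dir: str = "panelcal_out"
    data_path: str | None = None
    margins_path: str | None = None
    simulation: SimulationConfig | None = None
    columns: dict = field(default_factory=dict)
    design: SampleDesign | None = None
    propensity: PropensityConfig = field(default_factory=PropensityConfig)
    calibration: CalibrationSpec | None = None
    outcome: OutcomeSpec = field(default_factory=lambda: OutcomeSpec("y"))
    estimators: list = field(default_factory=list)
    bootstrap: dict = field(default_factory=dict)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        seed = int(raw.get("seed", 0))
        sim = None
        if raw.get("data") is None:
            sim_raw = dict(raw.get("simulation") or {})
            if "nonresponse" in sim_raw:
                sim_raw["nonresponse"] = NonResponseModel(**sim_raw["nonresponse"])
            else:
                sim_raw["nonresponse"] = NonResponseModel(
                    coefficients=DEFAULT_MAR_COEFFICIENTS
                )
            sim_raw.setdefault("seed", derive_seed(seed, 0))
            if "n_new" in sim_raw:
                sim_raw["n_new"] = {int(k): int(v) for k, v in sim_raw["n_new"].items()}
            sim = SimulationConfig(**sim_raw)
        design = None
        if raw.get("design"):
            d = raw["design"]
            design = SampleDesign(
                N=int(d["N"]),
                strata_sizes=d["strata_sizes"],
                n_new={int(j): v for j, v in d.get("n_new", {}).items()},
            )
        prop = PropensityConfig(**(raw.get("propensity") or {}))
        cal = None
        if raw.get("calibration"):
            c = dict(raw["calibration"])
            c.pop("margins", None)
            if "bounds" in c and c["bounds"] is not None:
                c["bounds"] = tuple(c["bounds"])
            cal = CalibrationSpec(margins=(), **c)
        out_raw = dict(raw.get("outcome") or {"column": "y"})
        pos = out_raw.get("positive_classes")
        outcome = OutcomeSpec(
            outcome=out_raw.get("column", "y"),
            positive_classes=frozenset(pos) if pos else None,
            sex_column=out_raw.get("sex_column", "sex"),
            women_label=out_raw.get("women_label", "W"),
            men_label=out_raw.get("men_label", "M"),
            same_epsilon=float(out_raw.get("same_epsilon", 0.0)),
        )
        return cls(
            seed=seed,
            output_dir=raw.get("output_dir", "panelcal_out"),
            data_path=raw.get("data"),
            margins_path=raw.get("margins"),
            simulation=sim,
            columns=raw.get("columns") or {},
            design=design,
            propensity=prop,
            calibration=cal,
            outcome=outcome,
            estimators=list(raw.get("estimators") or []),
            bootstrap=dict(raw.get("bootstrap") or {}),
        )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(pio.load_config(path))


# --------------------------------------------------------------------
# assembly
# --------------------------------------------------------------------

def build_inputs(cfg: RunConfig):
    """Load or simulate (dataset, margins, truth-or-None)."""
    if cfg.data_path is not None:
        cols = cfg.columns
        data = pio.read_panel(
            cfg.data_path,
            covariates=cols.get("covariates", ()),
            outcomes=cols.get("outcomes", ("y",)),
            margin_columns=cols.get("margins", ()),
            design=cfg.design,
        )
        if cfg.margins_path is None:
            raise ValueError("external data requires a margins file")
        margins = pio.read_margins(cfg.margins_path)
        return data, margins, None
    data, frame, truth = simulate_overlapping_panel(cfg.simulation)
    margins = population_margins(frame, DEFAULT_MARGINS)
    return data, margins, truth


def build_pipeline(
    cfg: RunConfig, data: PanelDataset, margins: Sequence[MarginTotals]
) -> WeightingPipeline:
    design = data.design or cfg.design
    if design is None:
        raise ValueError("a sample design is required (config or simulated)")
    return WeightingPipeline(
        design=design,
        margins=margins,
        propensity=cfg.propensity,
        calibration=cfg.calibration,
        seed=cfg.seed,
    )


# --------------------------------------------------------------------
# estimates
# --------------------------------------------------------------------

def _expand_requests(requests, t: int):
    """Yield (name, j, change_class) triples from the request list."""
    for req in requests:
        name = req["name"]
        measurements = req.get("measurements") or list(
            range(1, t + 1) if name in CROSS_SECTIONAL else range(2, t + 1)
        )
        classes = req.get("classes")
        for j in measurements:
            if name in ("gross_change", "long_gender_gap"):
                for a in classes or CHANGE_CLASSES:
                    yield name, int(j), a
            else:
                yield name, int(j), None


def scalar_estimate(
    pipeline: WeightingPipeline,
    data: PanelDataset,
    name: str,
    j: int,
    spec: OutcomeSpec,
    change_class: str | None = None,
    prefit=None,
    weights_cache: dict | None = None,
) -> Estimate:
    """Compute one named estimator from scratch on ``data``.

    ``weights_cache`` (keyed by ('cs'|'long', j)) avoids recomputing
    weight vectors when many estimators share them.
    """
    cache = weights_cache if weights_cache is not None else {}

    def cs_weights(m: int) -> WeightVector:
        key = ("cs", m)
        if key not in cache:
            pf = prefit.get(m) if prefit else None
            cache[key] = pipeline.cross_sectional(data, m, prefit=pf)[0]
        return cache[key]

    def long_weights(m: int) -> WeightVector:
        key = ("long", m)
        if key not in cache:
            pf = prefit.get(m) if prefit else None
            cache[key] = pipeline.longitudinal(data, m, prefit=pf)[0]
        return cache[key]

    if name == "total":
        return calibrated_total(cs_weights(j), data, spec, j)
    if name == "proportion":
        return calibrated_proportion(cs_weights(j), data, spec, j)
    if name in ("abs_change", "rel_change"):
        fn = calibrated_proportion if spec.positive_classes else calibrated_total
        est_j, est_1 = fn(cs_weights(j), data, spec, j), fn(cs_weights(1), data, spec, 1)
        return (
            absolute_change(est_j, est_1)
            if name == "abs_change"
            else relative_change(est_j, est_1)
        )
    if name == "gender_gap_abs":
        stat = "proportion" if spec.positive_classes else "total"
        return gender_gap_abs(cs_weights(j), data, spec, j, statistic=stat)
    if name == "gender_gap_rel":
        stat = "proportion" if spec.positive_classes else "total"
        return gender_gap_rel(cs_weights(j), data, spec, j, statistic=stat)
    if name == "long_diff":
        return longitudinal_difference(long_weights(j), data, spec, j)
    if name == "gross_change":
        return gross_change_count(long_weights(j), data, spec, j, change_class)
    if name == "rate":
        v = long_weights(j)
        dec = gross_change_count(v, data, spec, j, "decrease")
        inc = gross_change_count(v, data, spec, j, "increase")
        return deterioration_rate(dec, inc)
    if name in ("long_gender_gap_abs", "long_gender_gap_rel"):
        abs_gap, rel_gap = longitudinal_gender_gap(
            long_weights(j), data, spec, j, change_class
        )
        return abs_gap if name.endswith("abs") else rel_gap
    raise ValueError(f"unknown estimator {name!r}")


def compute_estimates(
    pipeline: WeightingPipeline,
    data: PanelDataset,
    cfg: RunConfig,
    cache: dict | None = None,
) -> tuple[list[Estimate], dict]:
    """All requested estimates, sharing one weights cache."""
    cache = cache if cache is not None else {}
    out: list[Estimate] = []
    t = data.n_measurements
    for name, j, a in _expand_requests(cfg.estimators, t):
        if name in ("abs_change", "rel_change") and j == 1:
            out.append(Estimate(0.0, name, (1, 1)))
            continue
        if name == "long_gender_gap":
            if ("long", j) not in cache:
                cache[("long", j)] = pipeline.longitudinal(data, j)[0]
            abs_gap, rel_gap = longitudinal_gender_gap(
                cache[("long", j)], data, cfg.outcome, j, a
            )
            out.extend([abs_gap, rel_gap])
            continue
        out.append(
            scalar_estimate(
                pipeline, data, name, j, cfg.outcome, a, weights_cache=cache
            )
        )
    return out, cache


# --------------------------------------------------------------------
# bootstrap over the full pipeline
# --------------------------------------------------------------------

def make_statistic(
    pipeline: WeightingPipeline,
    data: PanelDataset,
    name: str,
    j: int,
    spec: OutcomeSpec,
    change_class: str | None = None,
    refit_propensity: bool | None = None,
):
    """Statistic closure re-running the pipeline on any dataset.

    When propensity refitting is disabled (default for the boosted
    family), the models fitted on the original data re-score each
    replicate; otherwise every replicate refits from scratch.
    """
    if refit_propensity is None:
        refit_propensity = pipeline.propensity.family == "logistic"
    prefit = None
    if not refit_propensity:
        needed = {j}
        if name in ("abs_change", "rel_change"):
            needed.add(1)
        prefit = {m: pipeline.propensity_fits(data, m) for m in needed}

    def statistic(ds: PanelDataset) -> float:
        return scalar_estimate(
            pipeline, ds, name, j, spec, change_class, prefit=prefit
        ).value

    return statistic


def bootstrap_estimate(
    pipeline: WeightingPipeline,
    data: PanelDataset,
    name: str,
    j: int,
    spec: OutcomeSpec,
    change_class: str | None = None,
    boot: BootstrapConfig | None = None,
) -> Estimate:
    boot = boot or BootstrapConfig(seed=derive_seed(pipeline.seed, _TAG_BOOT, j))
    stat = make_statistic(
        pipeline, data, name, j, spec, change_class, boot.refit_propensity
    )
    est = bootstrap_ci(stat, data, boot, estimator_name=name)
    est.measurement = j
    return est


# --------------------------------------------------------------------
# the chained run
# --------------------------------------------------------------------

def run(raw_config: dict, output_dir: str | None = None) -> dict:
    """Execute the full pipeline and persist all outputs.

    Returns a dict with the dataset, weight vectors, diagnostics and
    the estimates table.
    """
    cfg = RunConfig.from_dict(raw_config)
    outdir = Path(output_dir or cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    data, margins, truth = build_inputs(cfg)
    pipeline = build_pipeline(cfg, data, margins)
    t = data.n_measurements
    log.info("dataset: %d rows, %d measurements", len(data.data), t)

    pio.write_panel(data, outdir / "panel.csv")
    pio.write_margins(margins, outdir / "margins.csv")
    if truth is not None:
        pio.dump_config({"truth": _jsonable(truth)}, outdir / "truth.yaml")

    diagnostics: dict = {"seed": cfg.seed, "measurements": {}}
    weight_vectors: list[WeightVector] = []
    cache: dict = {}
    for j in range(1, t + 1):
        w, info = pipeline.cross_sectional(data, j)
        cache[("cs", j)] = w
        weight_vectors.extend(info["components"])
        weight_vectors.append(info["combined"])
        weight_vectors.append(w)
        diagnostics["measurements"][j] = {
            "alphas": info["plan"].alphas.tolist(),
            "components": [list(map(str, c)) for c in info["plan"].components],
            "calibration": {
                k: v for k, v in info["calibration"].items() if k != "warning"
            },
            "hyperparameters": {
                str(k): f.best_params for k, f in info["fits"].items()
            },
            "cv_loss": {
                str(k): f.cv_loss for k, f in info["fits"].items()
            },
        }
        if j >= 2:
            v, vinfo = pipeline.longitudinal(data, j)
            cache[("long", j)] = v
            weight_vectors.append(v)
            diagnostics["measurements"][j]["longitudinal_calibration"] = {
                k: val for k, val in vinfo["calibration"].items() if k != "warning"
            }
        rep = margin_report(w, data.unit_table(data.margin_columns), margins)
        rep.to_csv(outdir / f"margin_report_m{j}.csv", index=False)

    pio.write_weights(weight_vectors, outdir / "weights.csv")

    estimates, _ = compute_estimates(pipeline, data, cfg, cache=cache)
    boot_raw = dict(cfg.bootstrap)
    if boot_raw.pop("enabled", False):
        boot = BootstrapConfig(
            **{**boot_raw, "seed": boot_raw.get("seed", derive_seed(cfg.seed, _TAG_BOOT))}
        )
        estimates = []
        for name, j, a in _expand_requests(cfg.estimators, t):
            if name in ("abs_change", "rel_change") and j == 1:
                estimates.append(Estimate(0.0, name, (1, 1)))
                continue
            names = (
                ("long_gender_gap_abs", "long_gender_gap_rel")
                if name == "long_gender_gap"
                else (name,)
            )
            for nm in names:
                estimates.append(
                    bootstrap_estimate(pipeline, data, nm, j, cfg.outcome, a, boot)
                )

    pio.write_estimates(estimates, outdir / "estimates.csv")
    pio.dump_config(_jsonable(diagnostics), outdir / "diagnostics.yaml")
    return {
        "data": data,
        "margins": margins,
        "truth": truth,
        "pipeline": pipeline,
        "weights": cache,
        "estimates": estimates,
        "diagnostics": diagnostics,
        "output_dir": str(outdir),
    }


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
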