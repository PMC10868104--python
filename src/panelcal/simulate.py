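"""Synthetic finite populations and overlapping-panel samples.

The generator emulates the sampling frame of a regional health panel
survey: a closed finite population stratified by province x degree of
urbanization, with calibration attributes (sex, age group, province,
urbanization, nationality), unit-level covariates, and an outcome
observed at every measurement. Samples are drawn by stratified simple
random sampling with allocation proportional to stratum population;
new samples at different measurements have empty pairwise
intersections; non-response is MCAR or MAR-logistic in the covariates
with the marginal rate pinned to a target by solving for the intercept.

Every simulated study carries its ground truth (totals, changes,
gender gaps, gross-change counts by full enumeration of the frame) so
downstream reweighting stages can be validated against known values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .dataset import PanelDataset, PanelDataError, SampleDesign


# --------------------------------------------------------------------
# configuration
# --------------------------------------------------------------------

@dataclass
class NonResponseModel:
    """Response mechanism: MCAR or covariate-dependent (MAR) logistic.

    ``coefficients`` are per-covariate log-odds contributions; an
    intercept is solved numerically per sample so that the *expected*
    marginal response rate equals the target. Targets can differ for
    new samples and for panel follow-ups, and per measurement.
    """

    mechanism: str = "mar_logistic"  # or "mcar"
    coefficients: Mapping[str, float] = field(default_factory=dict)
    rate_new: float | Mapping[int, float] = 0.7
    rate_panel: float | Mapping[tuple[int, int], float] = 0.8

    def __post_init__(self) -> None:
        if self.mechanism not in ("mcar", "mar_logistic"):
            raise PanelDataError(f"unknown mechanism {self.mechanism!r}")
        for r in self._all_rates():
            if not 0 < r <= 1:
                raise PanelDataError(f"target rate {r} outside (0, 1]")

    def _all_rates(self):
        for r in (self.rate_new, self.rate_panel):
            if isinstance(r, Mapping):
                yield from r.values()
            else:
                yield r

    def target_rate(self, panel: int, measurement: int) -> float:
        """Marginal response rate for panel i fielded at measurement j."""
        if measurement == panel:
            r = self.rate_new
            return float(r[measurement]) if isinstance(r, Mapping) else float(r)
        r = self.rate_panel
        return float(r[(panel, measurement)]) if isinstance(r, Mapping) else float(r)


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic overlapping-panel survey.

    Defaults emulate a four-measurement regional panel at desk scale:
    8 strata (4 provinces x 2 urbanization grades), a closed population
    of 20 000, theoretical new-sample sizes shrinking after the first
    measurement, and MAR-logistic non-response (rate 0.7 for fresh
    samples, 0.8 for panel follow-ups) driven by age and a continuous
    covariate that also drives the outcome.
    """

    N: int = 20_000
    t: int = 4
    strata_proportions: Mapping[str, float] = field(
        default_factory=lambda: {
            "P1|urban": 0.22, "P1|rural": 0.08,
            "P2|urban": 0.18, "P2|rural": 0.07,
            "P3|urban": 0.15, "P3|rural": 0.08,
            "P4|urban": 0.14, "P4|rural": 0.08,
        }
    )
    n_new: Mapping[int, int] = field(
        default_factory=lambda: {1: 750, 2: 640, 3: 750, 4: 750}
    )
    mean_shifts: Sequence[float] = (0.0, 0.15, 0.35, 0.5)
    covariate_effects: Mapping[str, float] = field(
        default_factory=lambda: {"x1": 1.0}
    )
    sex_effect: float = 0.3
    noise_scale: float = 1.0
    outcome_kind: str = "continuous"  # or "ordinal"
    ordinal_cuts: Sequence[float] = (-1.5, -0.5, 0.7, 1.8)
    nonresponse: NonResponseModel = field(default_factory=NonResponseModel)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.N <= 0:
            raise PanelDataError(f"N must be positive, got {self.N}")
        total = float(sum(self.strata_proportions.values()))
        if abs(total - 1.0) > 1e-9:
            raise PanelDataError(f"strata proportions sum to {total}, expected 1")
        if self.outcome_kind not in ("continuous", "ordinal"):
            raise PanelDataError(f"unknown outcome kind {self.outcome_kind!r}")
        if self.t < 1 or len(self.mean_shifts) < self.t:
            raise PanelDataError("need one mean shift per measurement")
        for j in range(1, self.t + 1):
            if self.n_new.get(j, 0) > self.N:
                raise PanelDataError(f"n_new[{j}] exceeds N")


#: Calibration margins used by the bundled study: sex crossed with each
#: auxiliary variable separately (not one full interaction table).
DEFAULT_MARGINS = (
    ("sex", "age_group"),
    ("sex", "province"),
    ("sex", "urbanization"),
    ("sex", "nationality"),
)


# --------------------------------------------------------------------
# allocation helpers
# --------------------------------------------------------------------

def largest_remainder(total: int, shares: Mapping[str, float]) -> dict[str, int]:
    """Integer apportionment of ``total`` by the largest-remainder rule.

    Ties in the fractional remainders are broken by key order.
    """
    keys = list(shares)
    denom = float(sum(shares.values()))
    quotas = np.array([total * shares[k] / denom for k in keys])
    base = np.floor(quotas).astype(int)
    short = total - int(base.sum())
    # stable sort: equal remainders keep key order
    order = np.argsort(-(quotas - base), kind="stable")
    for idx in order[:short]:
        base[idx] += 1
    return dict(zip(keys, base.tolist()))


# --------------------------------------------------------------------
# population
# --------------------------------------------------------------------

def generate_population(config: SimulationConfig) -> pd.DataFrame:
    """Build the closed finite population frame.

    Returns a DataFrame with one row per unit: stratum (province x
    urbanization), calibration attributes, covariates x1/x2 and the
    outcome at every measurement in columns ``y1..yt``. Outcomes follow
    a linear model in the covariates with a per-measurement mean shift;
    ordinal outcomes cut a logistic latent variable into 5 categories
    (1 best .. 5 worst).
    """
    rng = np.random.default_rng(config.seed)
    counts = largest_remainder(config.N, config.strata_proportions)

    strata = np.repeat(list(counts), list(counts.values()))
    frame = pd.DataFrame({"unit_id": np.arange(config.N), "stratum": strata})
    parts = frame["stratum"].str.split("|", expand=True)
    frame["province"], frame["urbanization"] = parts[0], parts[1]
    frame["sex"] = rng.choice(["M", "W"], size=config.N)
    frame["age_group"] = rng.choice(
        ["16-34", "35-54", "55+"], size=config.N, p=[0.30, 0.40, 0.30]
    )
    frame["nationality"] = rng.choice(["ES", "other"], size=config.N, p=[0.90, 0.10])
    frame["x1"] = rng.normal(size=config.N)
    frame["x2"] = rng.normal(size=config.N)
    # age carries signal so MAR-on-age biases outcomes
    age_code = frame["age_group"].map({"16-34": -1.0, "35-54": 0.0, "55+": 1.0})
    frame["x1"] += 0.5 * age_code

    eta0 = sum(
        config.covariate_effects.get(c, 0.0) * frame[c]
        for c in config.covariate_effects
    )
    eta0 = np.asarray(eta0, dtype=float) + config.sex_effect * (frame["sex"] == "W")
    for j in range(1, config.t + 1):
        eta = eta0 + config.mean_shifts[j - 1]
        if config.outcome_kind == "continuous":
            y = eta + (
                config.noise_scale * rng.normal(size=config.N)
                if config.noise_scale > 0
                else 0.0
            )
        else:
            latent = eta + rng.logistic(size=config.N)
            y = np.digitize(latent, config.ordinal_cuts) + 1  # 1..5
        frame[f"y{j}"] = y
    return frame


def population_margins(
    frame: pd.DataFrame, margins: Sequence[Sequence[str]] = DEFAULT_MARGINS
):
    """Population totals per calibration cell for each margin.

    Returns a list of :class:`~panelcal.calibrate.MarginTotals`.
    """
    from .calibrate import MarginTotals

    out = []
    for cols in margins:
        cols = tuple(cols)
        counts = frame.groupby(list(cols), observed=True).size()
        totals = {
            (k if isinstance(k, tuple) else (k,)): float(v)
            for k, v in counts.items()
        }
        out.append(MarginTotals(name="x".join(cols), columns=cols, totals=totals))
    return out


def enumerate_truth(frame: pd.DataFrame, t: int) -> dict:
    """Ground-truth parameters by full enumeration of the frame.

    Covers the whole estimator family: totals and means per
    measurement, absolute/relative change vs. measurement 1, gender
    gaps, consecutive-measurement differences, gross-change counts and
    deterioration rates, and longitudinal gender gaps per change class.
    """
    truth: dict = {"N": len(frame), "total": {}, "mean": {},
                   "gender_gap_abs": {}, "gender_gap_rel": {},
                   "abs_change": {}, "rel_change": {},
                   "long_diff": {}, "gross_change": {}, "rate": {},
                   "long_gender_gap_abs": {}, "long_gender_gap_rel": {}}
    is_w = (frame["sex"] == "W").to_numpy()
    for j in range(1, t + 1):
        y = frame[f"y{j}"].to_numpy(dtype=float)
        truth["total"][j] = float(y.sum())
        truth["mean"][j] = float(y.mean())
        gw, gm = float(y[is_w].sum()), float(y[~is_w].sum())
        truth["gender_gap_abs"][j] = gw - gm
        truth["gender_gap_rel"][j] = (gw - gm) / gm if gm else math.nan
        truth["abs_change"][j] = truth["total"][j] - truth["total"][1]
        truth["rel_change"][j] = truth["abs_change"][j] / truth["total"][1]
    for j in range(2, t + 1):
        d = frame[f"y{j}"].to_numpy(dtype=float) - frame[f"y{j-1}"].to_numpy(dtype=float)
        truth["long_diff"][j] = float(d.sum())
        inc, dec, same = (d > 0), (d < 0), (d == 0)
        truth["gross_change"][j] = {
            "increase": float(inc.sum()),
            "decrease": float(dec.sum()),
            "same": float(same.sum()),
        }
        truth["rate"][j] = (
            (dec.sum() - inc.sum()) / inc.sum() if inc.any() else math.nan
        )
        truth["long_gender_gap_abs"][j] = {}
        truth["long_gender_gap_rel"][j] = {}
        for name, mask in (("increase", inc), ("decrease", dec), ("same", same)):
            w_cnt = float((mask & is_w).sum())
            m_cnt = float((mask & ~is_w).sum())
            truth["long_gender_gap_abs"][j][name] = w_cnt - m_cnt
            truth["long_gender_gap_rel"][j][name] = (
                (w_cnt - m_cnt) / m_cnt if m_cnt else math.nan
            )
    return truth


# --------------------------------------------------------------------
# sampling & non-response
# --------------------------------------------------------------------

def draw_new_sample(
    frame: pd.DataFrame,
    n: int,
    rng: np.random.Generator,
    exclude: set | None = None,
) -> pd.DataFrame:
    """Stratified SRS of ``n`` units, proportional allocation, avoiding
    ``exclude`` so successive theoretical samples stay disjoint."""
    exclude = exclude or set()
    avail = frame.loc[~frame["unit_id"].isin(exclude)]
    if n > len(avail):
        raise PanelDataError(f"cannot draw {n} units from {len(avail)} available")
    sizes = frame.groupby("stratum", sort=True).size()
    alloc = largest_remainder(n, sizes.to_dict())
    chunks = []
    for h in sizes.index:  # fixed stratum order for reproducibility
        pool = avail.loc[avail["stratum"] == h, "unit_id"].to_numpy()
        n_h = alloc[h]
        if n_h > len(pool):
            raise PanelDataError(
                f"stratum {h}: need {n_h} units, only {len(pool)} available"
            )
        chunks.append(rng.choice(pool, size=n_h, replace=False))
    ids = np.concatenate(chunks) if chunks else np.array([], dtype=int)
    return frame.loc[frame["unit_id"].isin(ids)].copy()


def solve_mar_intercept(eta: np.ndarray, target_rate: float) -> float:
    """Intercept c with mean(expit(c + eta)) == target_rate (|gap|<1e-6)."""
    if target_rate >= 1.0:
        return np.inf

    def gap(c: float) -> float:
        return float(expit(c + eta).mean() - target_rate)

    lo, hi = -50.0, 50.0
    return float(brentq(gap, lo, hi, xtol=1e-9, rtol=8.9e-16, maxiter=200))


def apply_nonresponse(
    sample: pd.DataFrame,
    model: NonResponseModel,
    target_rate: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw response indicators delta ~ Bernoulli(m(x)) for a sample."""
    n = len(sample)
    if model.mechanism == "mcar" or not model.coefficients:
        prob = np.full(n, target_rate)
    else:
        eta = np.zeros(n)
        for col, coef in model.coefficients.items():
            x = sample[col]
            if x.dtype == object or isinstance(x.dtype, pd.CategoricalDtype):
                # categorical covariates enter through fixed codes
                x = x.astype("category").cat.codes.astype(float)
            eta += coef * np.asarray(x, dtype=float)
        c = solve_mar_intercept(eta, target_rate)
        prob = expit(c + eta) if np.isfinite(c) else np.ones(n)
    return (rng.random(n) < prob).astype(int)


#: MAR mechanism of the bundled study: older / high-x1 units respond less.
DEFAULT_MAR_COEFFICIENTS = {"x1": -0.8}


# --------------------------------------------------------------------
# the overlapping panel
# --------------------------------------------------------------------

def simulate_overlapping_panel(
    config: SimulationConfig,
) -> tuple[PanelDataset, pd.DataFrame, dict]:
    """Simulate a full overlapping-panel study.

    At each measurement j the survivors of every earlier panel (units
    that responded at all of M_i..M_{j-1}) are re-fielded and exposed
    to follow-up non-response, and a fresh sample disjoint from every
    earlier theoretical sample is drawn and exposed to first-contact
    non-response.

    Returns (dataset, population frame, ground-truth record).
    """
    ss = np.random.SeedSequence(config.seed)
    pop_seed, sample_seed = ss.spawn(2)
    frame = generate_population(replace(config, seed=int(pop_seed.generate_state(1)[0] % 2**31)))
    rng = np.random.default_rng(sample_seed)

    attr_cols = [
        "stratum", "province", "urbanization", "sex", "age_group",
        "nationality", "x1", "x2",
    ]
    sizes = frame.groupby("stratum", sort=True).size()
    indexed = frame.set_index("unit_id")
    n_new_strata: dict[int, dict[str, int]] = {}
    rows: list[pd.DataFrame] = []
    drawn: set = set()
    # survivors[i] = unit ids of panel i still fielded
    survivors: dict[int, np.ndarray] = {}

    for j in range(1, config.t + 1):
        # longitudinal part: survivors of each earlier panel
        for i in sorted(survivors):
            ids = survivors[i]
            part = frame.loc[frame["unit_id"].isin(ids), ["unit_id"] + attr_cols].copy()
            part = part.sort_values("unit_id")
            rate = config.nonresponse.target_rate(i, j)
            delta = apply_nonresponse(part, config.nonresponse, rate, rng)
            part["panel"], part["measurement"], part["delta"] = i, j, delta
            part["y"] = np.where(delta == 1, indexed.loc[part["unit_id"], f"y{j}"], np.nan)
            rows.append(part)
            survivors[i] = part.loc[part["delta"] == 1, "unit_id"].to_numpy()
        # fresh sample, disjoint from every earlier theoretical sample
        n_j = config.n_new.get(j, 0)
        if n_j > 0:
            new = draw_new_sample(frame, n_j, rng, exclude=drawn)
            drawn |= set(new["unit_id"])
            n_new_strata[j] = largest_remainder(n_j, sizes.to_dict())
            part = new[["unit_id"] + attr_cols].copy().sort_values("unit_id")
            rate = config.nonresponse.target_rate(j, j)
            delta = apply_nonresponse(part, config.nonresponse, rate, rng)
            part["panel"], part["measurement"], part["delta"] = j, j, delta
            part["y"] = np.where(delta == 1, indexed.loc[part["unit_id"], f"y{j}"], np.nan)
            rows.append(part)
            survivors[j] = part.loc[part["delta"] == 1, "unit_id"].to_numpy()

    data = pd.concat(rows, ignore_index=True)
    design = SampleDesign(
        N=config.N,
        strata_sizes=sizes.to_dict(),
        n_new=n_new_strata,
    )
    dataset = PanelDataset(
        data,
        covariates=["x1", "x2", "sex", "age_group", "province", "urbanization", "nationality"],
        outcomes=["y"],
        margin_columns=["sex", "age_group", "province", "urbanization", "nationality"],
        design=design,
    )
    truth = enumerate_truth(frame, config.t)
    return dataset, frame, truth
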