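"""Response-propensity modelling and PSA weight construction.

Non-response is assumed ignorable: the probability that a unit
responds depends only on observed covariates, P(delta=1 | y, x) =
m(x, lambda). The propensity m is fitted by a classifier — gradient
boosted trees (the default family) or logistic regression (a fast,
deterministic alternative used for large simulation studies).

Because response rates are rarely near 0.5, training uses *class
balancing*: instance weight (1-p)*delta_k + p*(1-delta_k), where p is
the observed response rate. Balancing distorts the output
probabilities, so raw scores are mapped back with

    pi_corrected = pi*p / (pi*p + (1-pi)*(1-p)),

which is the identity at p = 0.5 and strictly increasing in pi.

The corrected propensities then enter the PSA weights:

* new sample s^(j):   d_k = (N_h/n_h^(j)) * (n^(j)/n_r^(j)),
  weight = d_k / pi_k;
* panel i at j:       weight = (N/n_r^(i,j-1)) * (n_r^(i,j-1)/n_r^(i,j))
  / pi_k = N / (n_r^(i,j) * pi_k).

Hyperparameters of the boosted family are chosen by a seeded
randomized search over the configured ranges, scoring each candidate
by 5-fold label-stratified cross-validated weighted logistic loss.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import loguniform, randint, uniform
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.compose import ColumnTransformer
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import log_loss
from sklearn.model_selection import ParameterSampler, StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import OneHotEncoder

from .dataset import PanelDataset, SampleDesign, WeightVector
from .weights import EstimationError


class DegenerateFitError(ValueError):
    """Single-class labels: no propensity model can be fit.

    Fall back to the MCAR estimate pi == p (i.e. the response-rate
    adjustment) instead.
    """


def balance_weights(delta: np.ndarray) -> np.ndarray:
    """Class-balancing instance weights (1-p)*delta + p*(1-delta)."""
    delta = np.asarray(delta)
    p = delta.mean()
    return (1.0 - p) * delta + p * (1.0 - delta)


def correct_propensity(pi_hat, p: float):
    """Undo the probability distortion introduced by class balancing."""
    pi_hat = np.asarray(pi_hat, dtype=float)
    out = pi_hat * p / (pi_hat * p + (1.0 - pi_hat) * (1.0 - p))
    return float(out) if out.ndim == 0 else out


@dataclass
class PropensityConfig:
    """Settings for propensity model fitting.

    The search space for the boosted family: number of trees in
    [10, 1000], learning rate in [0.001, 0.9] (log scale), maximum
    depth in [1, 30], minimum child weight in [0, 10], subsample
    fraction in [0.6, 1]. ``clip`` bounds the corrected propensities
    to keep weight inflation finite.
    """

    family: str = "gradient_boosted_trees"  # or "logistic"
    n_trials: int = 50
    cv_folds: int = 5
    clip: tuple[float, float] = (0.02, 0.98)
    include_prior_outcomes: bool = True
    seed: int = 0
    search_space: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.family not in ("gradient_boosted_trees", "logistic"):
            raise ValueError(f"unknown model family {self.family!r}")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        lo, hi = self.clip
        if not 0 < lo < hi < 1:
            raise ValueError("clip bounds must satisfy 0 < lo < hi < 1")

    def distributions(self) -> dict:
        if self.search_space:
            return dict(self.search_space)
        return {
            "n_estimators": randint(10, 1001),
            "learning_rate": loguniform(0.001, 0.9),
            "max_depth": randint(1, 31),
            "min_child_weight": uniform(0, 10),
            "subsample": uniform(0.6, 0.4),
        }


@dataclass
class PropensityFit:
    """A fitted response-propensity model and its per-unit scores."""

    raw: pd.Series          # clipped classifier scores, index = unit_id
    corrected: pd.Series    # after the class-balance correction
    p: float                # observed response rate
    best_params: dict
    cv_loss: float | None
    seed: int
    model: object = None


class ResponsePropensityClassifier(BaseEstimator, ClassifierMixin):
    """Sklearn-style response-propensity model with class balancing.

    ``fit(X, delta)`` trains the configured family with class-balanced
    instance weights (after a cross-validated randomized
    hyperparameter search for the boosted family) and stores the raw
    and corrected propensities of the training rows.

    Attributes (after fit)
    ----------------------
    p_ : observed response rate.
    best_params_ : chosen hyperparameters (empty for logistic).
    cv_loss_ : mean CV weighted logistic loss of the chosen candidate.
    propensities_raw_, propensities_ : per-row scores (corrected ones
        clipped to ``clip``).
    """

    def __init__(
        self,
        family: str = "gradient_boosted_trees",
        n_trials: int = 50,
        cv_folds: int = 5,
        clip: tuple[float, float] = (0.02, 0.98),
        seed: int = 0,
        search_space: Mapping[str, object] | None = None,
    ):
        self.family = family
        self.n_trials = n_trials
        self.cv_folds = cv_folds
        self.clip = clip
        self.seed = seed
        self.search_space = search_space

    # -- internals ----------------------------------------------------

    def _config(self) -> PropensityConfig:
        return PropensityConfig(
            family=self.family,
            n_trials=self.n_trials,
            cv_folds=self.cv_folds,
            clip=self.clip,
            seed=self.seed,
            search_space=self.search_space or {},
        )

    def _encoder(self, X: pd.DataFrame) -> ColumnTransformer:
        cat = [c for c in X.columns if X[c].dtype == object or str(X[c].dtype) == "category"]
        num = [c for c in X.columns if c not in cat]
        return ColumnTransformer(
            [
                ("num", "passthrough", num),
                ("cat", OneHotEncoder(handle_unknown="ignore"), cat),
            ]
        )

    def _base_model(self, params: dict):
        if self.family == "logistic":
            return LogisticRegression(max_iter=2000)
        from xgboost import XGBClassifier

        return XGBClassifier(
            objective="binary:logistic",
            eval_metric="logloss",
            tree_method="hist",
            n_jobs=1,
            random_state=self.seed,
            **params,
        )

    # -- API ----------------------------------------------------------

    def fit(self, X: pd.DataFrame, y, sample_weight=None):
        cfg = self._config()
        X = pd.DataFrame(X).reset_index(drop=True)
        delta = np.asarray(y).astype(int)
        classes = np.unique(delta)
        if len(classes) < 2:
            raise DegenerateFitError(
                "labels contain a single class; fall back to the MCAR "
                "propensity pi == p (response-rate adjustment)"
            )
        self.p_ = float(delta.mean())
        bw = balance_weights(delta)

        best_params: dict = {}
        best_loss: float | None = None
        if self.family == "gradient_boosted_trees" and self.n_trials > 0:
            sampler = ParameterSampler(
                cfg.distributions(), n_iter=self.n_trials, random_state=self.seed
            )
            skf = StratifiedKFold(
                n_splits=self.cv_folds, shuffle=True, random_state=self.seed
            )
            splits = list(skf.split(X, delta))
            for params in sampler:
                losses = []
                for tr, va in splits:
                    model = Pipeline(
                        [("enc", self._encoder(X)), ("clf", self._base_model(params))]
                    )
                    model.fit(
                        X.iloc[tr], delta[tr], clf__sample_weight=bw[tr]
                    )
                    prob = model.predict_proba(X.iloc[va])[:, 1]
                    losses.append(
                        log_loss(delta[va], prob, sample_weight=bw[va], labels=[0, 1])
                    )
                mean_loss = float(np.mean(losses))
                if best_loss is None or mean_loss < best_loss:
                    best_loss, best_params = mean_loss, dict(params)
        self.best_params_ = best_params
        self.cv_loss_ = best_loss

        self.model_ = Pipeline(
            [("enc", self._encoder(X)), ("clf", self._base_model(best_params))]
        )
        self.model_.fit(X, delta, clf__sample_weight=bw)

        lo, hi = self.clip
        raw = np.clip(self.model_.predict_proba(X)[:, 1], lo, hi)
        corrected = np.clip(correct_propensity(raw, self.p_), lo, hi)
        self.propensities_raw_ = raw
        self.propensities_ = corrected
        return self

    def predict_proba(self, X):
        return self.model_.predict_proba(pd.DataFrame(X))

    def predict(self, X):
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)

    def corrected_propensity(self, X) -> np.ndarray:
        """Clipped, balance-corrected propensities for new rows."""
        lo, hi = self.clip
        raw = np.clip(self.predict_proba(X)[:, 1], lo, hi)
        return np.clip(correct_propensity(raw, self.p_), lo, hi)


def fit_propensity(
    training_rows: pd.DataFrame,
    delta,
    config: PropensityConfig,
    covariates: Sequence[str] | None = None,
) -> PropensityFit:
    """Fit a propensity model on one training set.

    ``training_rows`` must be indexed (or indexable) by unit_id via a
    ``unit_id`` column; ``covariates`` defaults to every non-label
    column.
    """
    ids = training_rows["unit_id"].to_numpy()
    cols = list(covariates) if covariates is not None else [
        c for c in training_rows.columns if c not in ("unit_id", "delta")
    ]
    clf = ResponsePropensityClassifier(
        family=config.family,
        n_trials=config.n_trials,
        cv_folds=config.cv_folds,
        clip=config.clip,
        seed=config.seed,
        search_space=config.search_space or None,
    )
    clf.fit(training_rows[cols], delta)
    return PropensityFit(
        raw=pd.Series(clf.propensities_raw_, index=ids),
        corrected=pd.Series(clf.propensities_, index=ids),
        p=clf.p_,
        best_params=clf.best_params_,
        cv_loss=clf.cv_loss_,
        seed=config.seed,
        model=clf,
    )


def mcar_fallback_fit(training_rows: pd.DataFrame, delta, seed: int = 0) -> PropensityFit:
    """Constant propensity pi == p, for degenerate (single-class) labels
    or as an explicit no-information baseline."""
    ids = training_rows["unit_id"].to_numpy()
    delta = np.asarray(delta).astype(int)
    p = float(delta.mean()) if len(delta) else 1.0
    const = pd.Series(np.full(len(ids), max(p, 1e-12)), index=ids)
    return PropensityFit(
        raw=const.copy(), corrected=const, p=p,
        best_params={}, cv_loss=None, seed=seed,
    )


# --------------------------------------------------------------------
# PSA weights
# --------------------------------------------------------------------

def psa_weights_new(
    design: SampleDesign,
    data: PanelDataset,
    fit: PropensityFit,
    j: int,
) -> WeightVector:
    """PSA weights for the new effective sample s_r^(j).

    weight_k = (N_h / n_h^(j)) * (n^(j) / n_r^(j)) / pi_k with the
    corrected propensity pi_k.
    """
    resp = data.respondents(j, panel=j)
    n = data.fielded_size(j, panel=j)
    n_r = len(resp)
    if n_r == 0:
        raise EstimationError(f"no respondents in the new sample at measurement {j}")
    n_h = design.n_new[j]
    d = resp["stratum"].map(
        {h: design.strata_sizes[h] / n_h[h] for h in n_h}
    ).to_numpy(dtype=float)
    pi = fit.corrected.loc[resp["unit_id"]].to_numpy()
    w = d * (n / n_r) / pi
    return WeightVector(
        pd.Series(w, index=resp["unit_id"].to_numpy()),
        stage="psa", measurement=j, panel=j,
    )


def psa_weights_panel(
    design: SampleDesign,
    data: PanelDataset,
    fit: PropensityFit,
    i: int,
    j: int,
) -> WeightVector:
    """PSA weights for panel i's effective sample s_r^(i,j) at j.

    weight_k = (N / n_r^(i,j-1)) * (n_r^(i,j-1) / n_r^(i,j)) / pi_k
             = N / (n_r^(i,j) * pi_k).
    """
    if not i < j:
        raise ValueError("panel weights require i < j")
    resp = data.respondents(j, panel=i)
    n_r_ij = len(resp)
    if n_r_ij == 0:
        raise EstimationError(f"panel {i} has no respondents at measurement {j}")
    pi = fit.corrected.loc[resp["unit_id"]].to_numpy()
    w = design.N / (n_r_ij * pi)
    return WeightVector(
        pd.Series(w, index=resp["unit_id"].to_numpy()),
        stage="psa", measurement=j, panel=i,
    )


def panel_training_rows(
    data: PanelDataset, i: int, j: int, include_prior_outcomes: bool = True
) -> tuple[pd.DataFrame, np.ndarray]:
    """Training set for panel i's response at measurement j.

    Rows are the units fielded at j (the survivors s_r^(i,j-1)), with
    frame covariates and, optionally, their outcomes observed at
    measurements i..j-1; labels are their response indicators at j.
    """
    fielded = data.rows(j, panel=i)
    cols = ["unit_id"] + list(data.covariates)
    rows = fielded[cols].copy()
    if include_prior_outcomes:
        for y in data.outcomes:
            wide = data.outcome_wide(y)
            for m in range(i, j):
                if m in wide.columns:
                    rows[f"{y}_m{m}"] = wide[m].reindex(rows["unit_id"]).to_numpy()
    return rows, fielded["delta"].to_numpy()
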