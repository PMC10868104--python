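"""Class balancing, the probability correction, propensity fitting and
PSA weight formulas."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import spearmanr

from panelcal.dataset import PanelDataset, SampleDesign
from panelcal.propensity import (
    DegenerateFitError,
    PropensityConfig,
    ResponsePropensityClassifier,
    balance_weights,
    correct_propensity,
    fit_propensity,
    mcar_fallback_fit,
    psa_weights_new,
    psa_weights_panel,
)
from panelcal.simulate import NonResponseModel, apply_nonresponse, generate_population, SimulationConfig


class TestBalanceWeights:
    def test_balanced_labels_give_half(self):
        assert np.allclose(balance_weights(np.array([0, 1, 0, 1])), 0.5)

    def test_direct_formula(self):
        w = balance_weights(np.array([1, 1, 1, 0]))
        assert np.allclose(w, [0.25, 0.25, 0.25, 0.75])

    @given(st.lists(st.integers(0, 1), min_size=2, max_size=200).filter(
        lambda ls: 0 < sum(ls) < len(ls)))
    @settings(deadline=None, max_examples=50)
    def test_classes_contribute_equal_total_weight(self, labels):
        delta = np.array(labels)
        w = balance_weights(delta)
        p = delta.mean()
        n = len(delta)
        assert w[delta == 1].sum() == pytest.approx(p * (1 - p) * n)
        assert w[delta == 0].sum() == pytest.approx(p * (1 - p) * n)


class TestCorrectPropensity:
    def test_identity_at_half(self):
        assert correct_propensity(0.9, 0.5) == pytest.approx(0.9)

    def test_symmetric_point_gives_half(self):
        assert correct_propensity(0.8, 0.2) == pytest.approx(0.5)

    def test_inverse_round_trip(self):
        for pi in (0.01, 0.3, 0.77, 0.99):
            for p in (0.1, 0.5, 0.9):
                back = correct_propensity(correct_propensity(pi, p), 1 - p)
                assert back == pytest.approx(pi, abs=1e-12)

    def test_monotone_in_both_arguments(self):
        grid = np.linspace(0.01, 0.99, 25)
        for p in (0.2, 0.5, 0.8):
            vals = correct_propensity(grid, p)
            assert np.all(np.diff(vals) > 0)
        for pi in (0.2, 0.5, 0.8):
            vals = np.array([correct_propensity(pi, p) for p in grid])
            assert np.all(np.diff(vals) > 0)
        assert np.all((correct_propensity(grid, 0.3) > 0) & (correct_propensity(grid, 0.3) < 1))


def _mar_training_data(n=2000, seed=0, coef=1.5, rate=0.6):
    rng = np.random.default_rng(seed)
    x = rng.normal(size=n)
    frame = pd.DataFrame({"unit_id": np.arange(n), "x1": x})
    model = NonResponseModel(mechanism="mar_logistic", coefficients={"x1": coef})
    delta = apply_nonresponse(frame, model, rate, rng)
    return frame, delta


class TestFitPropensity:
    def test_no_information_limit_recovers_rate(self):
        # constant covariates: corrected propensity ~ observed rate
        rng = np.random.default_rng(1)
        n = 2000
        rows = pd.DataFrame({"unit_id": np.arange(n), "x1": np.zeros(n)})
        delta = (rng.random(n) < 0.7).astype(int)
        fit = fit_propensity(rows, delta, PropensityConfig(family="logistic"))
        assert np.all(np.abs(fit.corrected - delta.mean()) < 0.02)

    def test_mar_mechanism_recovery(self):
        frame, delta = _mar_training_data(n=4000, seed=2)
        fit = fit_propensity(frame, delta, PropensityConfig(family="logistic"))
        from scipy.special import expit
        from panelcal.simulate import solve_mar_intercept

        eta = 1.5 * frame["x1"].to_numpy()
        true_m = expit(solve_mar_intercept(eta, 0.6) + eta)
        rho = spearmanr(fit.corrected.to_numpy(), true_m).statistic
        assert rho > 0.8

    def test_boosted_family_deterministic_under_seed(self):
        frame, delta = _mar_training_data(n=400, seed=5)
        cfg = PropensityConfig(
            family="gradient_boosted_trees", n_trials=3, seed=99
        )
        f1 = fit_propensity(frame, delta, cfg)
        f2 = fit_propensity(frame, delta, cfg)
        assert f1.best_params == f2.best_params
        assert np.allclose(f1.corrected, f2.corrected)
        assert f1.cv_loss == pytest.approx(f2.cv_loss)

    def test_boosted_search_space_respected(self):
        frame, delta = _mar_training_data(n=300, seed=6)
        cfg = PropensityConfig(family="gradient_boosted_trees", n_trials=2, seed=1)
        fit = fit_propensity(frame, delta, cfg)
        hp = fit.best_params
        assert 10 <= hp["n_estimators"] <= 1000
        assert 0.001 <= hp["learning_rate"] <= 0.9
        assert 1 <= hp["max_depth"] <= 30
        assert 0 <= hp["min_child_weight"] <= 10
        assert 0.6 <= hp["subsample"] <= 1.0
        assert fit.cv_loss is not None and fit.cv_loss > 0

    def test_single_class_raises_degenerate(self):
        rows = pd.DataFrame({"unit_id": [0, 1, 2], "x1": [0.0, 1.0, 2.0]})
        with pytest.raises(DegenerateFitError):
            fit_propensity(rows, np.ones(3), PropensityConfig(family="logistic"))
        fb = mcar_fallback_fit(rows, np.ones(3))
        assert np.allclose(fb.corrected, 1.0)

    def test_propensities_respect_clip_bounds(self):
        frame, delta = _mar_training_data(n=1000, seed=7, coef=5.0)
        cfg = PropensityConfig(family="logistic", clip=(0.05, 0.95))
        fit = fit_propensity(frame, delta, cfg)
        assert fit.corrected.min() >= 0.05 and fit.corrected.max() <= 0.95

    def test_sklearn_param_interface(self):
        clf = ResponsePropensityClassifier(family="logistic", seed=3)
        params = clf.get_params()
        assert params["family"] == "logistic"
        clf.set_params(seed=5)
        assert clf.seed == 5


def _psa_dataset(n, n_r, N, panel=1, measurement=1):
    delta = [1] * n_r + [0] * (n - n_r)
    df = pd.DataFrame(
        {
            "unit_id": range(n),
            "panel": panel,
            "measurement": measurement,
            "stratum": "A",
            "delta": delta,
            "y": [1.0 if d else np.nan for d in delta],
        }
    )
    design = SampleDesign(N=N, strata_sizes={"A": N}, n_new={1: {"A": n}})
    return PanelDataset(df, outcomes=["y"], design=design), design


class TestPsaWeights:
    def test_full_response_unit_propensity_equals_design(self):
        data, design = _psa_dataset(n=200, n_r=200, N=10_000)
        fit = mcar_fallback_fit(data.data[["unit_id"]], np.ones(200))
        w = psa_weights_new(design, data, fit, 1)
        assert np.allclose(w.weights, 50.0)

    def test_new_sample_weight_arithmetic(self):
        # N=10000, n=200, n_r=160, pi=0.8 -> 50 * 1.25 * 1.25 = 78.125
        data, design = _psa_dataset(n=200, n_r=160, N=10_000)
        ids = data.respondents(1, panel=1)["unit_id"]
        fit = mcar_fallback_fit(data.data[["unit_id"]], np.ones(200))
        fit.corrected = pd.Series(0.8, index=data.data["unit_id"])
        w = psa_weights_new(design, data, fit, 1)
        assert np.allclose(w.weights, 78.125)
        assert set(w.weights.index) == set(ids)

    def test_panel_weight_arithmetic(self):
        # N=8000, n_r^(1,2)=320, pi=0.8 -> 8000/320/0.8 = 31.25
        data, design = _psa_dataset(n=400, n_r=320, N=8_000, panel=1, measurement=2)
        fit = mcar_fallback_fit(data.data[["unit_id"]], np.ones(400))
        fit.corrected = pd.Series(0.8, index=data.data["unit_id"])
        w = psa_weights_panel(design, data, fit, 1, 2)
        assert np.allclose(w.weights, 31.25)

    def test_panel_constant_propensity_total_identity(self):
        # pi == n_r^(i,j)/n_r^(i,j-1) makes the y==1 total equal N exactly
        data, design = _psa_dataset(n=400, n_r=320, N=8_000, panel=1, measurement=2)
        fit = mcar_fallback_fit(data.data[["unit_id"]], np.ones(400))
        fit.corrected = pd.Series(320 / 400, index=data.data["unit_id"])
        w = psa_weights_panel(design, data, fit, 1, 2)
        assert w.total == pytest.approx(8_000 / (320 / 400), rel=1e-12)
        # and with pi == 1 the weight is N/n_r for all respondents
        fit.corrected = pd.Series(1.0, index=data.data["unit_id"])
        w1 = psa_weights_panel(design, data, fit, 1, 2)
        assert np.allclose(w1.weights, 8_000 / 320)

    def test_psa_weights_dominate_design_weights(self):
        data, design = _psa_dataset(n=200, n_r=150, N=10_000)
        rng = np.random.default_rng(0)
        fit = mcar_fallback_fit(data.data[["unit_id"]], np.ones(200))
        fit.corrected = pd.Series(
            rng.uniform(0.3, 1.0, size=200), index=data.data["unit_id"]
        )
        w = psa_weights_new(design, data, fit, 1)
        assert np.all(w.weights.to_numpy() >= 50.0 - 1e-9)
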