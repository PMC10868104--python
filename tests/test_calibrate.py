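"""Raking/GREG calibration against brute-force oracles and its
feasibility diagnostics."""

import numpy as np
import pandas as pd
import pytest

from panelcal.calibrate import (
    CalibrationError,
    CalibrationSpec,
    MarginTotals,
    RakingCalibrator,
    calibrate,
    margin_report,
    rake_arrays,
)
from panelcal.dataset import WeightVector


def brute_force_ipf(d, cells_per_margin, targets_per_margin, iters=2000):
    """Plain-dict IPF, written independently of the package solver."""
    w = list(map(float, d))
    for _ in range(iters):
        for cells, targets in zip(cells_per_margin, targets_per_margin):
            sums = {}
            for wi, c in zip(w, cells):
                sums[c] = sums.get(c, 0.0) + wi
            w = [wi * targets[c] / sums[c] for wi, c in zip(w, cells)]
    return np.array(w)


def _margin(name, cols, totals):
    return MarginTotals(name=name, columns=cols, totals=totals)


class TestRaking:
    def test_fixed_point_weights_unchanged(self):
        mem = pd.DataFrame({"g": ["a", "a", "b", "b"]}, index=[1, 2, 3, 4])
        m = _margin("g", ("g",), {("a",): 50.0, ("b",): 50.0})
        w = WeightVector(pd.Series([25.0] * 4, index=[1, 2, 3, 4]), "combined", 1)
        out, diag = calibrate(w, mem, CalibrationSpec(margins=[m]))
        assert np.allclose(out.weights, 25.0)
        assert diag["iterations"] == 0 and diag["converged"]

    def test_single_margin_exact_proportional_scaling(self):
        mem = pd.DataFrame({"g": ["A", "A", "B", "B"]}, index=list(range(4)))
        m = _margin("g", ("g",), {("A",): 60.0, ("B",): 40.0})
        w = WeightVector(pd.Series([25.0] * 4, index=range(4)), "combined", 1)
        out, diag = calibrate(w, mem, CalibrationSpec(margins=[m]))
        assert np.allclose(out.weights, [30, 30, 20, 20])
        assert diag["converged"]

    def test_two_crossed_margins_match_brute_force_ipf(self, rng):
        # randomized toys, truncation disabled
        for trial in range(5):
            n = 16
            g1 = rng.choice(["a", "b"], n)
            g2 = rng.choice(["x", "y"], n)
            d = rng.uniform(5, 40, n)
            t1 = {("a",): 300.0, ("b",): 200.0}
            t2 = {("x",): 260.0, ("y",): 240.0}
            mem = pd.DataFrame({"g1": g1, "g2": g2}, index=range(n))
            spec = CalibrationSpec(
                margins=[
                    _margin("g1", ("g1",), t1),
                    _margin("g2", ("g2",), t2),
                ],
                bounds=None,
                tolerance=1e-12,
            )
            w = WeightVector(pd.Series(d, index=range(n)), "combined", 1)
            out, diag = calibrate(w, mem, spec)
            oracle = brute_force_ipf(
                d,
                [list(g1), list(g2)],
                [
                    {"a": 300.0, "b": 200.0},
                    {"x": 260.0, "y": 240.0},
                ],
            )
            assert np.allclose(out.weights.to_numpy(), oracle, atol=1e-6)

    def test_complete_margin_forces_population_total(self):
        mem = pd.DataFrame({"g": ["A", "A", "B"]}, index=range(3))
        m = _margin("g", ("g",), {("A",): 70.0, ("B",): 30.0})
        w = WeightVector(pd.Series([30.0, 25.0, 20.0], index=range(3)), "combined", 1)
        out, _ = calibrate(w, mem, CalibrationSpec(margins=[m]))
        assert out.total == pytest.approx(100.0)

    def test_truncation_bounds_respected(self):
        mem = pd.DataFrame({"g": ["A", "B"]}, index=range(2))
        m = _margin("g", ("g",), {("A",): 90.0, ("B",): 10.0})
        d = pd.Series([20.0, 20.0], index=range(2))
        spec = CalibrationSpec(margins=[m], bounds=(0.5, 2.0))
        out, diag = calibrate(WeightVector(d, "combined", 1), mem, spec)
        ratios = out.weights / d
        assert ratios.max() <= 2.0 + 1e-9 and ratios.min() >= 0.5 - 1e-9
        assert not diag["converged"]  # targets unreachable inside bounds
        assert diag["n_truncated"] >= 1
        assert diag["warning"] is not None

    def test_empty_cell_with_positive_target_raises(self):
        mem = pd.DataFrame({"g": ["A", "A"]}, index=range(2))
        m = _margin("g", ("g",), {("A",): 60.0, ("B",): 40.0})
        w = WeightVector(pd.Series([25.0, 25.0], index=range(2)), "combined", 1)
        with pytest.raises(CalibrationError, match="B"):
            calibrate(w, mem, CalibrationSpec(margins=[m]))

    def test_unknown_sample_cell_raises(self):
        mem = pd.DataFrame({"g": ["A", "C"]}, index=range(2))
        m = _margin("g", ("g",), {("A",): 60.0, ("B",): 40.0})
        w = WeightVector(pd.Series([25.0, 25.0], index=range(2)), "combined", 1)
        with pytest.raises(CalibrationError):
            calibrate(w, mem, CalibrationSpec(margins=[m]))


class TestGreg:
    def test_linear_distance_matches_direct_solution(self, rng):
        # oracle: solve the GREG system directly in the test
        n = 12
        g1 = rng.choice(["a", "b"], n)
        d = rng.uniform(5, 20, n)
        X = np.column_stack([(g1 == "a").astype(float), (g1 == "b").astype(float)])
        targets = np.array([80.0, 60.0])
        lam = np.linalg.solve(X.T @ (d[:, None] * X), targets - X.T @ d)
        oracle = d * (1 + X @ lam)

        mem = pd.DataFrame({"g1": g1}, index=range(n))
        spec = CalibrationSpec(
            margins=[_margin("g1", ("g1",), {("a",): 80.0, ("b",): 60.0})],
            distance="linear",
            bounds=None,
        )
        out, diag = calibrate(
            WeightVector(pd.Series(d, index=range(n)), "combined", 1), mem, spec
        )
        assert np.allclose(out.weights.to_numpy(), oracle, atol=1e-8)
        assert diag["converged"]

    def test_linear_equals_raking_in_the_small_adjustment_limit(self, rng):
        # both distances agree to first order when targets ~ achieved
        n = 30
        g = rng.choice(["a", "b"], n)
        d = np.full(n, 10.0)
        base_a = float(d[g == "a"].sum())
        base_b = float(d[g == "b"].sum())
        totals = {("a",): base_a * 1.01, ("b",): base_b * 0.99}
        mem = pd.DataFrame({"g": g}, index=range(n))
        wv = WeightVector(pd.Series(d, index=range(n)), "combined", 1)
        raked, _ = calibrate(
            wv, mem, CalibrationSpec(margins=[_margin("g", ("g",), totals)], bounds=None)
        )
        greg, _ = calibrate(
            wv, mem,
            CalibrationSpec(
                margins=[_margin("g", ("g",), totals)], distance="linear", bounds=None
            ),
        )
        assert np.allclose(raked.weights, greg.weights, rtol=1e-3)


class TestMarginReport:
    def test_calibrated_weights_meet_tolerance(self):
        mem = pd.DataFrame({"g": ["A", "A", "B"]}, index=range(3))
        m = _margin("g", ("g",), {("A",): 70.0, ("B",): 30.0})
        w = WeightVector(pd.Series([30.0, 25.0, 20.0], index=range(3)), "combined", 1)
        out, _ = calibrate(w, mem, CalibrationSpec(margins=[m]))
        rep = margin_report(out, mem, [m])
        assert (rep["rel_error"].abs() < 1e-6).all()

    def test_biased_weights_show_margin_error(self):
        mem = pd.DataFrame({"g": ["A", "A", "B"]}, index=range(3))
        m = _margin("g", ("g",), {("A",): 70.0, ("B",): 30.0})
        w = pd.Series([10.0, 10.0, 40.0], index=range(3))  # B overweighted
        rep = margin_report(w, mem, [m])
        assert (rep["rel_error"].abs() > 1e-6).any()

    def test_empty_margin_list_gives_empty_report(self):
        rep = margin_report(pd.Series([1.0], index=[0]), pd.DataFrame(index=[0]), [])
        assert rep.empty


class TestSpecValidation:
    def test_bad_bounds_rejected(self):
        with pytest.raises(ValueError):
            CalibrationSpec(margins=[], bounds=(1.5, 3.0))

    def test_bad_distance_rejected(self):
        with pytest.raises(ValueError):
            CalibrationSpec(margins=[], distance="entropy")

    def test_nonpositive_target_rejected(self):
        with pytest.raises(CalibrationError):
            MarginTotals("g", ("g",), {("a",): 0.0})


def test_rake_arrays_skips_structurally_empty_cells():
    # the low-level core tolerates cells absent from the sample
    d = np.array([10.0, 10.0])
    codes = np.array([0, 0])  # cell 1 empty
    targets = np.array([30.0, 40.0])
    w, diag = rake_arrays(d, [(codes, targets)], bounds=None)
    assert np.allclose(w, [15.0, 15.0])
    assert diag["converged"]
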