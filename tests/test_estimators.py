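"""Point estimators: arithmetic, partition identities, symmetry nulls
and recovery of enumerated truth."""

import numpy as np
import pandas as pd
import pytest

from panelcal.dataset import PanelDataset, WeightVector
from panelcal.estimators import (
    Estimate,
    OutcomeSpec,
    UndefinedRatioError,
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


def _cs_dataset(weights, y, sex=None, j=1):
    n = len(weights)
    sex = sex or ["M"] * n
    df = pd.DataFrame(
        {
            "unit_id": range(n),
            "panel": 1,
            "measurement": j,
            "stratum": "A",
            "delta": 1,
            "sex": sex,
            "y": y,
        }
    )
    data = PanelDataset(df, outcomes=["y"], margin_columns=["sex"])
    w = WeightVector(pd.Series(weights, index=range(n), dtype=float), "calibrated", j)
    return data, w


def _long_dataset(v, y1, y2, sex=None):
    n = len(v)
    sex = sex or ["M"] * n
    rows = []
    for j, ys in ((1, y1), (2, y2)):
        rows.append(
            pd.DataFrame(
                {
                    "unit_id": range(n),
                    "panel": 1,
                    "measurement": j,
                    "stratum": "A",
                    "delta": 1,
                    "sex": sex,
                    "y": ys,
                }
            )
        )
    data = PanelDataset(pd.concat(rows), outcomes=["y"], margin_columns=["sex"])
    w = WeightVector(pd.Series(v, index=range(n), dtype=float), "calibrated", 2)
    return data, w


SPEC = OutcomeSpec("y")


class TestCrossSectional:
    def test_total_weighted_sum(self):
        data, w = _cs_dataset([30, 30, 20, 20], [1, 0, 1, 0])
        assert calibrated_total(w, data, SPEC, 1).value == pytest.approx(50.0)

    def test_proportion_and_complement(self):
        data, w = _cs_dataset([30, 30, 20, 20], [1, 0, 1, 0])
        spec = OutcomeSpec("y", positive_classes=frozenset([1]))
        p = calibrated_proportion(w, data, spec, 1)
        assert p.value == pytest.approx(0.5)
        spec_c = OutcomeSpec("y", positive_classes=frozenset([0]))
        q = calibrated_proportion(w, data, spec_c, 1)
        assert p.value + q.value == pytest.approx(1.0)

    def test_all_in_class_gives_one(self):
        data, w = _cs_dataset([10, 10], [1, 1])
        spec = OutcomeSpec("y", positive_classes=frozenset([1]))
        assert calibrated_proportion(w, data, spec, 1).value == pytest.approx(1.0)

    def test_changes_arithmetic_and_identity(self):
        e1 = Estimate(10.0, "total", 1)
        ej = Estimate(12.0, "total", 4)
        assert absolute_change(ej, e1).value == pytest.approx(2.0)
        assert relative_change(ej, e1).value == pytest.approx(0.2)
        assert absolute_change(e1, e1).value == 0.0
        assert relative_change(ej, e1).value == pytest.approx(
            absolute_change(ej, e1).value / e1.value
        )

    def test_zero_baseline_raises(self):
        with pytest.raises(UndefinedRatioError):
            relative_change(Estimate(5.0, "total", 2), Estimate(0.0, "total", 1))

    def test_gender_gaps(self):
        data, w = _cs_dataset(
            [30, 30, 20, 20], [2, 1, 1, 1], sex=["W", "W", "M", "M"]
        )
        gap = gender_gap_abs(w, data, SPEC, 1)
        assert gap.value == pytest.approx(90 - 40)
        rel = gender_gap_rel(w, data, SPEC, 1)
        assert rel.value == pytest.approx(50 / 40)
        assert np.sign(rel.value) == np.sign(gap.value)

    def test_gender_gap_equals_domain_difference(self):
        data, w = _cs_dataset(
            [30, 30, 20, 20], [2, 1, 1, 3], sex=["W", "M", "W", "M"]
        )
        gap = gender_gap_abs(w, data, SPEC, 1)
        tw = calibrated_total(
            w, data, OutcomeSpec("y", domain={"sex": ["W"]}), 1
        ).value
        tm = calibrated_total(
            w, data, OutcomeSpec("y", domain={"sex": ["M"]}), 1
        ).value
        assert gap.value == pytest.approx(tw - tm, rel=1e-12)

    def test_men_zero_total_raises(self):
        data, w = _cs_dataset([10, 10], [1, 1], sex=["W", "W"])
        with pytest.raises(UndefinedRatioError):
            gender_gap_rel(w, data, SPEC, 1)


class TestLongitudinal:
    def test_no_change_gives_zero(self):
        data, v = _long_dataset([2, 3], [1.0, 2.0], [1.0, 2.0])
        assert longitudinal_difference(v, data, SPEC, 2).value == 0.0

    def test_weighted_difference(self):
        data, v = _long_dataset([2, 3], [0.0, 1.0], [1.0, 0.0])
        assert longitudinal_difference(v, data, SPEC, 2).value == pytest.approx(-1.0)

    def test_gross_change_counts(self):
        data, v = _long_dataset(
            [1, 1, 1, 1], [0, 2, 0, 0], [1, 0, 0, 3]
        )  # diffs 1, -2, 0, 3
        inc = gross_change_count(v, data, SPEC, 2, "increase")
        dec = gross_change_count(v, data, SPEC, 2, "decrease")
        same = gross_change_count(v, data, SPEC, 2, "same")
        assert (inc.value, dec.value, same.value) == (2, 1, 1)

    def test_partition_identity(self, rng):
        n = 40
        data, v = _long_dataset(
            rng.uniform(1, 5, n),
            rng.integers(1, 5, n).astype(float),
            rng.integers(1, 5, n).astype(float),
        )
        parts = [
            gross_change_count(v, data, SPEC, 2, a).value
            for a in ("increase", "decrease", "same")
        ]
        assert sum(parts) == pytest.approx(v.total, abs=1e-9)

    def test_all_same_outcomes(self):
        data, v = _long_dataset([2, 5], [1.0, 1.0], [1.0, 1.0])
        assert gross_change_count(v, data, SPEC, 2, "same").value == pytest.approx(7)
        assert gross_change_count(v, data, SPEC, 2, "increase").value == 0.0

    def test_deterioration_rate(self):
        rate = deterioration_rate(
            Estimate(30.0, "gross_decrease", (2, 1)), Estimate(20.0, "gross_increase", (2, 1))
        )
        assert rate.value == pytest.approx(0.5)
        assert deterioration_rate(
            Estimate(20.0, "d", 2), Estimate(20.0, "i", 2)
        ).value == 0.0
        assert deterioration_rate(
            Estimate(0.0, "d", 2), Estimate(20.0, "i", 2)
        ).value == pytest.approx(-1.0)
        with pytest.raises(UndefinedRatioError):
            deterioration_rate(Estimate(5.0, "d", 2), Estimate(0.0, "i", 2))

    def test_longitudinal_gender_gap_arithmetic(self):
        data, v = _long_dataset(
            [55, 50], [0.0, 0.0], [1.0, 1.0], sex=["W", "M"]
        )
        abs_gap, rel_gap = longitudinal_gender_gap(v, data, SPEC, 2, "increase")
        assert abs_gap.value == pytest.approx(5.0)
        assert rel_gap.value == pytest.approx(0.1)

    def test_gender_gap_partition_over_classes(self, rng):
        n = 60
        sex = list(rng.choice(["M", "W"], n))
        data, v = _long_dataset(
            rng.uniform(1, 5, n),
            rng.integers(1, 5, n).astype(float),
            rng.integers(1, 5, n).astype(float),
            sex=sex,
        )
        gaps = []
        for a in ("increase", "decrease", "same"):
            g, _ = longitudinal_gender_gap(v, data, SPEC, 2, a)
            gaps.append(g.value)
        is_w = np.array(sex) == "W"
        wv = v.weights.to_numpy()
        expect = wv[is_w].sum() - wv[~is_w].sum()
        assert sum(gaps) == pytest.approx(expect, abs=1e-9)

    def test_missing_prior_outcome_rejected(self):
        # unit present at j but not respondent at j-1 cannot enter
        df = pd.DataFrame(
            {
                "unit_id": [0, 0],
                "panel": [1, 1],
                "measurement": [1, 2],
                "stratum": "A",
                "delta": [0, 1],
                "sex": "M",
                "y": [np.nan, 1.0],
            }
        )
        data = PanelDataset(df, outcomes=["y"], margin_columns=["sex"])
        v = WeightVector(pd.Series([2.0], index=[0]), "calibrated", 2)
        with pytest.raises(ValueError):
            longitudinal_difference(v, data, SPEC, 2)


class TestRecovery:
    def test_symmetric_population_null_gender_gap(self, rng):
        # outcome law identical by sex => gap fluctuates around 0
        gaps = []
        for r in range(200):
            n = 200
            sex = rng.choice(["M", "W"], n)
            y = rng.normal(size=n)
            data, w = _cs_dataset(np.full(n, 10.0), y, sex=list(sex))
            gaps.append(gender_gap_abs(w, data, SPEC, 1).value)
        se = np.std(gaps, ddof=1) / np.sqrt(len(gaps))
        assert abs(np.mean(gaps)) < 3 * se + 1e-9

    def test_full_enumeration_total(self, full_response_study):
        # weights = N/n per unit under full response reproduce the
        # population mean scale; exact for cell-constant outcomes
        cfg, data, frame, truth = full_response_study
        from panelcal.simulate import population_margins
        from panelcal.propensity import PropensityConfig
        from panelcal.pipeline import WeightingPipeline

        margins = population_margins(frame, [("sex", "age_group")])
        pl = WeightingPipeline(
            design=data.design, margins=margins,
            propensity=PropensityConfig(family="logistic"), seed=0,
        )
        w, _ = pl.cross_sectional(data, 1)
        # indicator of a calibration cell is recovered exactly
        spec = OutcomeSpec("sex", positive_classes=frozenset(["W"]))
        est = calibrated_total(w, data, spec, 1)
        true_count = float((frame["sex"] == "W").sum())
        assert est.value == pytest.approx(true_count, rel=1e-9)
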