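import numpy as np
import pytest

from panelcal.propensity import PropensityConfig
from panelcal.simulate import (
    NonResponseModel,
    SimulationConfig,
    population_margins,
    simulate_overlapping_panel,
)
from panelcal.pipeline import WeightingPipeline


@pytest.fixture(scope="session")
def small_study():
    """A t=3 overlapping panel with MAR non-response and known truth."""
    cfg = SimulationConfig(
        N=4000,
        t=3,
        n_new={1: 250, 2: 200, 3: 250},
        nonresponse=NonResponseModel(coefficients={"x1": -0.8}),
        seed=42,
    )
    data, frame, truth = simulate_overlapping_panel(cfg)
    return cfg, data, frame, truth


@pytest.fixture(scope="session")
def small_pipeline(small_study):
    cfg, data, frame, truth = small_study
    margins = population_margins(frame)
    return WeightingPipeline(
        design=data.design,
        margins=margins,
        propensity=PropensityConfig(family="logistic"),
        seed=7,
    )


@pytest.fixture(scope="session")
def full_response_study():
    """A t=2 panel with no non-response (identity weighting path)."""
    cfg = SimulationConfig(
        N=3000,
        t=2,
        n_new={1: 200, 2: 150},
        nonresponse=NonResponseModel(
            mechanism="mcar", rate_new=1.0, rate_panel=1.0
        ),
        seed=11,
    )
    data, frame, truth = simulate_overlapping_panel(cfg)
    return cfg, data, frame, truth


@pytest.fixture(scope="session")
def ordinal_study():
    """A t=3 panel with a 5-category ordinal outcome (health-scale style)."""
    cfg = SimulationConfig(
        N=4000,
        t=3,
        n_new={1: 250, 2: 200, 3: 250},
        outcome_kind="ordinal",
        nonresponse=NonResponseModel(coefficients={"x1": -0.6}),
        seed=97,
    )
    data, frame, truth = simulate_overlapping_panel(cfg)
    return cfg, data, frame, truth


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
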