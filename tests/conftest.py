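import numpy as np
import pytest

from nabassay.bka import CurveRole, GrowthCurve
from nabassay.config import DEFAULT_TIME_GRID
from nabassay.synth import CohortSimConfig, GrowthModelParams, simulate_cohort, simulate_growth_curve


@pytest.fixture
def noiseless_curve() -> GrowthCurve:
    """Flat lag at 0.05 until 5 h, then +0.1 OD/h to a 0.9 plateau.

    The true crossing of OD 0.3 is at 7.5 h.
    """
    params = GrowthModelParams(baseline_od=0.05, carrying_capacity=0.9, lag_h=5.0, rate=0.1)
    return simulate_growth_curve(params, DEFAULT_TIME_GRID, seed=0)


@pytest.fixture
def flat_curve() -> GrowthCurve:
    return GrowthCurve(
        sample_id="flat",
        role=CurveRole.PLASMA,
        times=DEFAULT_TIME_GRID,
        od=(0.05,) * len(DEFAULT_TIME_GRID),
    )


@pytest.fixture(scope="session")
def small_cohort():
    """A small but complete simulated study (12 animals per population)."""
    return simulate_cohort(CohortSimConfig(n_per_population=(12, 12), seed=7))
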