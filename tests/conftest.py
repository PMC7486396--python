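import numpy as np
import pytest

from citydemog import (
    DemographicRates,
    MigrationModel,
    PopulationState,
    build_environment,
)


@pytest.fixture
def two_city_env():
    """Hand-checkable 2-city environment: A = [[0.9, 0.2], [0.1, 0.8]]."""
    rates = DemographicRates.from_vital([0.0, 0.0])
    mig = MigrationModel(np.array([[0.0, 0.1], [0.2, 0.0]]))
    return build_environment(rates, mig)


@pytest.fixture
def two_city_state():
    return PopulationState(np.array([100.0, 100.0]))


def random_valid_environment(rng, n, vital_scale=0.01, out_total=0.3):
    """Random strongly-mixing environment for oracle comparisons."""
    m = rng.random((n, n)) * out_total / (n - 1)
    np.fill_diagonal(m, 0.0)
    vital = vital_scale * rng.standard_normal(n)
    return build_environment(DemographicRates.from_vital(vital), MigrationModel(m))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
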