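import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from treatval import RngState, builtin_scenario, generate_validation_pair

settings.register_profile(
    "ci", derandomize=True, suppress_health_check=[HealthCheck.too_slow], deadline=None
)
settings.load_profile("ci")

#: Master seed for every stochastic test in the suite.
MASTER_SEED = 20170714


@pytest.fixture(scope="session")
def master_seed():
    return MASTER_SEED


@pytest.fixture(scope="session")
def sc1():
    return builtin_scenario("scenario_1")


@pytest.fixture(scope="session")
def sc1_pair(sc1):
    """One (development, validation) cohort pair under the default scenario."""
    return generate_validation_pair(sc1, RngState(MASTER_SEED, "fixtures/sc1"))


@pytest.fixture()
def rng():
    return np.random.default_rng(MASTER_SEED)
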