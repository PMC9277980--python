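import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from discountkit.staircase import StaircaseConfig
from discountkit.synthdata import CohortConfig, generate_cohort

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def staircase_config() -> StaircaseConfig:
    return StaircaseConfig()


@pytest.fixture(scope="session")
def small_cohort():
    """A 600-participant cohort under default study conditions, seed 11."""
    return generate_cohort(CohortConfig(n_participants=600, seed=11))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20210716)
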