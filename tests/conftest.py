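import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from loadfatigue.io import LoadingType, Slope, TrialCondition

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20240301)


@pytest.fixture(scope="session")
def condition_a_flat():
    return TrialCondition(LoadingType.A, Slope.FLAT)


@pytest.fixture(scope="session")
def short_trial(condition_a_flat):
    """A short calibrated synthetic trial shared across IO tests."""
    from loadfatigue.simulate import generate_trial

    return generate_trial(condition_a_flat, seed=11, duration=60.0)
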