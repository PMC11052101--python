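import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from lipedema_rmr import Cohort, default_config, generate_cohort

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_cohort() -> Cohort:
    """Default synthetic study-sized cohort (n=119, fixed seed)."""
    return generate_cohort(default_config(n=119, seed=42))


@pytest.fixture(scope="session")
def large_cohort() -> Cohort:
    """A calibration-sized cohort for distributional checks."""
    return generate_cohort(default_config(n=100_000, seed=7))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
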