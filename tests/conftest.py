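import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from sleepfrag import Hypnogram

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

STATES = ("WAKE", "NREM", "REM")


def random_hypnogram(rng: np.random.Generator, max_len: int = 500,
                     min_len: int = 1) -> Hypnogram:
    n = int(rng.integers(min_len, max_len + 1))
    labels = rng.choice(STATES, size=n)
    artifact = rng.random(n) < 0.05
    return Hypnogram(states=labels, artifact=artifact)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_cohort():
    """8 susceptible + 8 resilient baseline recordings, fixed seed."""
    import sleepfrag as sf

    return sf.simulate_cohort(n_per_group=8, seed=42)
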