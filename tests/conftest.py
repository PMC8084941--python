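import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_pair():
    """A tiny deterministic two-fly trajectory: female walks 0.5 mm/frame
    along x at 60 Hz, male parked 5 mm away."""
    from flybehave import Arena, PairTrajectory

    n = 60
    x = 0.5 * np.arange(n) - 15.0
    female = np.column_stack([x, np.zeros(n)])
    male = np.column_stack([x, np.full(n, 5.0)])
    return PairTrajectory(np.arange(n), 60.0, female, male, Arena(diameter_mm=40.0))
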