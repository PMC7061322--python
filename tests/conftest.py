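import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def noisy_series(rng):
    """A plausible learner's latency series: power-law decay plus noise."""
    from navlearn import simulate_latency_series

    return simulate_latency_series(
        a=48.0, b=-0.35, plateau=14, noise_sd=0.1, late_noise_sd=0.4, rng=rng
    )
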