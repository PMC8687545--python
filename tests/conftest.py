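import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from centroidmsd import OutreachDistribution, Uniform

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def default_dist():
    """Length uniform on [0, 10], angle uniform on [-30, 30] degrees."""
    return OutreachDistribution()


@pytest.fixture
def isotropic_dist():
    """Same length law, but an isotropic angle so E[eta] = 0."""
    return OutreachDistribution(angle_deg=Uniform(0.0, 360.0))
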