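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
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def pink_images():
    """Small 1/f-noise corpus shared across tests."""
    from uwica.synthetic import gen_pink_noise

    return [gen_pink_noise(128, seed=10 + i) for i in range(4)]
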