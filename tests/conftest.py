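import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=40,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_phantom():
    """A 32x32 noisy two-modality phantom used across integration tests."""
    from dpmseg.synthetic import PhantomSpec, make_phantom

    spec = PhantomSpec(shape=(32, 32), core_radius=5, edema_radius=9,
                       noise_sigma=0.05, seed=11)
    return make_phantom(spec)
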