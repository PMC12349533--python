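import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import drrpose as d

settings.register_profile(
    "suite", derandomize=True, max_examples=40, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_volume(rng):
    """Small random volume with anisotropic spacing and off-centre origin."""
    data = rng.random((12, 10, 14))
    return d.Volume(data=data, spacing=(1.0, 1.5, 0.8), origin=(-3.0, 2.0, -5.0))


@pytest.fixture(scope="session")
def small_phantom_spec():
    """Down-scaled spine phantom (48^3 at 2 mm) for fast pipeline tests."""
    base = d.default_phantom_spec(noise_sd=5.0, seed=7)
    return d.PhantomSpec(
        shape=(48, 48, 48), spacing=(2.0, 2.0, 2.0), noise_sd=5.0, seed=7, primitives=base.primitives
    )


@pytest.fixture(scope="session")
def small_phantom(small_phantom_spec):
    return d.generate_phantom_volume(small_phantom_spec)


@pytest.fixture(scope="session")
def small_geometry():
    return d.make_default_geometry("frontal", shape=(64, 64), pixel_spacing=3.0, step=2.0)
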