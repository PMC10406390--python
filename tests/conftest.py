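import numpy as np
import pytest
from hypothesis import settings

from mmoblique import AcquisitionConfig, PhantomParams, generate_phantom_mm

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


def small_params(**overrides) -> PhantomParams:
    """A fast phantom: 240 px image, analysis ring at radius 100."""
    defaults = dict(
        image_size=(240, 240),
        ring_radius=100.0,
        ring_half_width=10.0,
        incidence_theta=0.0,
        noise_sigma=0.0,
        seed=0,
    )
    defaults.update(overrides)
    return PhantomParams(**defaults)


@pytest.fixture(scope="session")
def clean_phantom():
    """Undistorted, noiseless phantom image at normal incidence."""
    return generate_phantom_mm(small_params())


@pytest.fixture
def acq():
    return AcquisitionConfig()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
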