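import numpy as np
import pytest

from zsdenoise import Image, NoiseSpec, PhantomSpec, corrupt, make_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def random_image(rng):
    """A 32 x 32 normalized random frame."""
    return Image(rng.random((32, 32)), source_range=(0.0, 1.0), normalized=True)


@pytest.fixture(scope="session")
def clean_phantom_128():
    """The benchmark phantom: 128 px, core 0.7, background 0.1, texture 0.05."""
    return make_phantom(
        PhantomSpec(
            size=128,
            core_intensity=0.7,
            background_intensity=0.1,
            texture_amplitude=0.05,
            seed=1,
        )
    )


@pytest.fixture(scope="session")
def noisy_phantom_128(clean_phantom_128):
    """The phantom under Gaussian read noise, sigma 0.1."""
    return corrupt(clean_phantom_128, NoiseSpec(gaussian_sigma=0.1, seed=2))
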