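import numpy as np
import pytest

from blurbench import (
    GrayImage,
    dog_profile,
    generate_surrogate_image,
    hex_mosaic,
    sample_windows,
)


@pytest.fixture(scope="session")
def small_images():
    """Three small 1/f surrogate images, enough for 25px windows with margin."""
    return [generate_surrogate_image(96, 64, 1.0, seed=500 + i) for i in range(3)]


@pytest.fixture(scope="session")
def mosaic():
    return hex_mosaic()


@pytest.fixture(scope="session")
def profile():
    return dog_profile()


@pytest.fixture(scope="session")
def windows(small_images):
    """Fifty 25x25 windows with margin 4 from the small surrogates."""
    return sample_windows(small_images, 50, 25, margin=4, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def random_window(rng):
    return GrayImage(rng.uniform(0.0, 1.0, size=(25, 25)))
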