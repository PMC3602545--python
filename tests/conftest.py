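import numpy as np
import pytest

from slfcmap import generate_atlas


@pytest.fixture(scope="session")
def small_atlas():
    """A 4-region atlas on a desk-size grid; seed region is PrL."""
    return generate_atlas((20, 10, 20), 4, rng_seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def texture_image(shape=(64, 64), seed=0, sigma=1.5):
    """Dense smooth texture (windowed filtered noise): enough unique
    structure that a rigid registration problem has one clear optimum,
    fading to zero at the frame so border cropping is negligible."""
    import scipy.ndimage as ndi
    rng = np.random.default_rng(seed)
    img = ndi.gaussian_filter(rng.normal(size=shape), sigma)
    window = np.outer(np.hanning(shape[0]), np.hanning(shape[1]))
    return img * window * 100
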