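import numpy as np
import pytest
from scipy import ndimage


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def smooth_image(rng):
    """A smooth random texture, the benign case for interpolated sampling."""
    return ndimage.gaussian_filter(rng.uniform(0, 255, (48, 48)), 1.5)


@pytest.fixture
def random_uint8(rng):
    return rng.integers(0, 256, (32, 32)).astype(np.uint8)
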