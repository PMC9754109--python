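import numpy as np
import pytest
from scipy import ndimage

from dfcc.io_preprocess import ImageSequence


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_texture(shape=(64, 64), sigma=2.0, seed=0):
    """Smooth positive random texture on [0.1, 1], periodic."""
    g = np.random.default_rng(seed)
    tex = ndimage.gaussian_filter(g.normal(size=shape), sigma, mode="wrap")
    tex = (tex - tex.min()) / (tex.max() - tex.min())
    return 0.1 + 0.9 * tex


@pytest.fixture
def textured_sequence():
    """A 4-frame static textured movie, 64x64, 65 nm pixels at 5 fps."""
    tex = make_texture()
    return ImageSequence(np.stack([tex] * 4), pixel_size_nm=65.0, frame_interval_s=0.2)
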