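import numpy as np
import pytest

from slsm3d import BinaryMask, PhantomSpec, ScalarVolume, make_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def clean_phantom():
    """Noise-free, unblurred default phantom (sphere r=10 in 64 cubed)."""
    return make_phantom(PhantomSpec())


@pytest.fixture
def small_volume(rng):
    return ScalarVolume(rng.normal(size=(8, 8, 8)))


def digital_ball(shape, center, radius):
    """Boolean ball by voxel-center distance; brute-force reference shape."""
    x, y, z = np.ogrid[: shape[0], : shape[1], : shape[2]]
    d2 = (x - center[0]) ** 2 + (y - center[1]) ** 2 + (z - center[2]) ** 2
    return d2 <= radius**2


@pytest.fixture
def ball_mask():
    return BinaryMask(digital_ball((32, 32, 32), (15.5, 15.5, 15.5), 10).astype(np.uint8))
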