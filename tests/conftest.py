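import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def two_blob_data():
    """Six 1-D points forming two clean blobs near 0.1 and 0.9."""
    return np.array([0.0, 0.1, 0.2, 0.8, 0.9, 1.0])


@pytest.fixture
def disk_mask():
    """Centered rasterized disk of radius 20 in a 51x51 grid."""
    n = 51
    yy, xx = np.mgrid[:n, :n]
    c = n // 2
    return (yy - c) ** 2 + (xx - c) ** 2 <= 20**2


def make_disk(radius, pad=5):
    n = 2 * radius + 2 * pad + 1
    yy, xx = np.mgrid[:n, :n]
    c = n // 2
    return (yy - c) ** 2 + (xx - c) ** 2 <= radius**2


def make_square(side, pad=5):
    n = side + 2 * pad
    m = np.zeros((n, n), dtype=bool)
    m[pad : pad + side, pad : pad + side] = True
    return m
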