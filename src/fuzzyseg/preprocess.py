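"""Intensity normalization, smoothing/median filtering, noise injection, image I/O.

All filters operate on float images in [0, 1] and use reflected borders.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from scipy import ndimage

__all__ = [
    "NoiseSpec",
    "normalize_intensity",
    "gaussian_smooth",
    "median_filter",
    "add_noise",
    "read_image",
    "write_image",
]


@dataclass(frozen=True)
class NoiseSpec:
    """Noise injection request: kind, percent level and the seed used."""

    kind: str  # "salt_pepper" | "gaussian"
    level: float  # percent, in (0, 100)
    seed: int = 0

    def __post_init__(self):
        if self.kind not in ("salt_pepper", "gaussian"):
            raise ValueError(f"unknown noise kind {self.kind!r}")
        if not 0 < self.level < 100:
            raise ValueError("noise level must be in (0, 100) percent")


def normalize_intensity(raw, bit_depth=None, max_value=None) -> np.ndarray:
    """Linearly rescale a raw image to [0, 1].

    With ``bit_depth`` (8 or 16) divides by ``2**bit_depth - 1``; with an
    explicit ``max_value`` divides by it; otherwise min-max scales, mapping a
    constant image to all zeros.
    """
    arr = np.asarray(raw, dtype=float)
    if arr.size == 0:
        raise ValueError("empty image")
    if bit_depth is not None:
        if bit_depth not in (8, 16):
            raise ValueError("bit_depth must be 8 or 16")
        return arr / (2**bit_depth - 1)
    if max_value is not None:
        if max_value <= 0:
            raise ValueError("max_value must be positive")
        return arr / max_value
    lo, hi = arr.min(), arr.max()
    if hi == lo:
        return np.zeros_like(arr)
    return (arr - lo) / (hi - lo)


def _check_odd(size: int):
    if size % 2 == 0 or size < 1:
        raise ValueError(f"window size must be odd and positive, got {size}")


def gaussian_smooth(image, size: int = 5, sigma: float = 2.0) -> np.ndarray:
    """Convolve with a normalized size-by-size Gaussian kernel (reflect borders)."""
    _check_odd(size)
    img = np.asarray(image, dtype=float)
    half = size // 2
    ax = np.arange(-half, half + 1, dtype=float)
    g = np.exp(-(ax**2) / (2.0 * sigma**2))
    kernel = np.outer(g, g)
    kernel /= kernel.sum()
    return ndimage.convolve(img, kernel, mode="reflect")


def median_filter(image, size: int = 3) -> np.ndarray:
    """Window median of each pixel (reflect borders)."""
    _check_odd(size)
    return ndimage.median_filter(np.asarray(image, dtype=float), size=size, mode="reflect")


def add_noise(image, spec: NoiseSpec) -> np.ndarray:
    """Corrupt an image according to a :class:`NoiseSpec`.

    Salt-and-pepper: exactly ``round(level/100 * N)`` pixels drawn without
    replacement are set to 0 or 1 with equal probability.  Gaussian: additive
    zero-mean noise with sigma = level/100 of the unit intensity range,
    clipped back to [0, 1].
    """
    img = np.asarray(image, dtype=float).copy()
    rng = np.random.default_rng(spec.seed)
    if spec.kind == "salt_pepper":
        n = img.size
        n_corrupt = int(round(spec.level / 100.0 * n))
        idx = rng.choice(n, size=n_corrupt, replace=False)
        values = rng.integers(0, 2, size=n_corrupt).astype(float)
        flat = img.ravel()
        flat[idx] = values
        return flat.reshape(img.shape)
    noisy = img + rng.normal(0.0, spec.level / 100.0, size=img.shape)
    return np.clip(noisy, 0.0, 1.0)


def read_image(path) -> np.ndarray:
    """Read a PGM or PNG image and normalize intensities to [0, 1]."""
    path = Path(path)
    arr = iio.imread(path)
    if arr.ndim == 3:  # collapse RGB(A) to luminance
        arr = arr[..., :3].mean(axis=2)
    if arr.dtype == np.uint8:
        return normalize_intensity(arr, bit_depth=8)
    if arr.dtype == np.uint16:
        return normalize_intensity(arr, bit_depth=16)
    return np.clip(np.asarray(arr, dtype=float), 0.0, 1.0)


def write_image(path, image) -> None:
    """Write a [0, 1] float image as an 8-bit PGM or PNG."""
    path = Path(path)
    img = np.clip(np.asarray(image, dtype=float), 0.0, 1.0)
    data = np.round(img * 255).astype(np.uint8)
    iio.imwrite(path, data)
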