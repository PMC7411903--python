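"""Seeded phantom mammogram generator.

Each phantom is a bright lesion embedded in a textured tissue region on a
dark background, with a three-class ground truth (background / tissue /
lesion).  Benign lesions are smooth near-elliptical blobs; malignant lesions
carry irregular harmonic boundary modulation plus radial spicules and a
slightly heavier internal texture, so shape descriptors (circularity, shape
factor, radial-length spread) carry the class signal.  Everything is
deterministic given the seed.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

from fuzzyseg.preprocess import NoiseSpec, add_noise, write_image

__all__ = ["Phantom", "make_phantom", "make_labeled_dataset", "noise_sweep_suite"]

BACKGROUND, TISSUE, LESION = 0, 1, 2

_BG_LEVEL = 0.15
_TISSUE_LEVEL = 0.50
# per-class texture scale relative to the texture_sd argument: background is
# the noisiest region, tissue the most homogeneous, lesions in between
_TEX_SCALE = {BACKGROUND: 1.6, TISSUE: 0.6, LESION: 1.2}
_MALIGNANT_TEX = 1.2  # extra lesion texture for malignant phantoms


@dataclass
class Phantom:
    image: np.ndarray  # [0, 1] float
    truth_labels: np.ndarray  # {0 background, 1 tissue, 2 lesion}
    truth_mask: np.ndarray  # lesion mask
    label: str  # "benign" | "malignant"
    seed: int
    noise: NoiseSpec | None = None


def _lesion_radius(theta, r0, kind, rng, spicule_count):
    """Angle-dependent lesion radius; irregular for malignant lesions."""
    r = np.full_like(theta, r0, dtype=float)
    if kind == "benign":
        for j in (2, 3):
            amp = rng.uniform(0.02, 0.05)
            r += r0 * amp * np.cos(j * theta + rng.uniform(0, 2 * np.pi))
        return r
    for j in range(2, 9):
        amp = rng.uniform(0.05, 0.22) / np.sqrt(j)
        r += r0 * amp * np.cos(j * theta + rng.uniform(0, 2 * np.pi))
    centers = rng.uniform(0, 2 * np.pi, size=spicule_count)
    amps = rng.uniform(0.25, 0.5, size=spicule_count)
    width = 0.06
    for c, a in zip(centers, amps):
        d = np.angle(np.exp(1j * (theta - c)))
        r += r0 * a * np.exp(-(d**2) / (2 * width**2))
    return r


def make_phantom(
    size: int = 128,
    kind: str = "benign",
    contrast: float = 0.35,
    texture_sd: float = 0.05,
    spicule_count: int = 10,
    seed: int = 0,
) -> Phantom:
    """Generate one phantom image with its three-class ground truth."""
    if kind not in ("benign", "malignant"):
        raise ValueError(f"invalid class {kind!r}")
    if size < 64:
        raise ValueError("size must be >= 64")
    rng = np.random.default_rng(seed)

    yy, xx = np.mgrid[:size, :size].astype(float)
    cy = cx = (size - 1) / 2.0

    # tissue: large tilted ellipse
    phi = rng.uniform(0, np.pi)
    a_t, b_t = size * 0.42, size * 0.36
    yr = (yy - cy) * np.cos(phi) + (xx - cx) * np.sin(phi)
    xr = -(yy - cy) * np.sin(phi) + (xx - cx) * np.cos(phi)
    tissue = (yr / a_t) ** 2 + (xr / b_t) ** 2 <= 1.0

    # lesion: star-shaped region around a jittered center inside the tissue
    lc_y = cy + rng.uniform(-0.05, 0.05) * size
    lc_x = cx + rng.uniform(-0.05, 0.05) * size
    r0 = size * rng.uniform(0.18, 0.22)
    theta = np.arctan2(yy - lc_y, xx - lc_x)
    dist = np.hypot(yy - lc_y, xx - lc_x)
    lesion = (dist <= _lesion_radius(theta, r0, kind, rng, spicule_count)) & tissue

    labels = np.zeros((size, size), dtype=np.int64)
    labels[tissue] = TISSUE
    labels[lesion] = LESION

    image = np.full((size, size), _BG_LEVEL)
    image[tissue] = _TISSUE_LEVEL
    image[lesion] = _TISSUE_LEVEL + contrast

    texture = ndimage.gaussian_filter(rng.normal(0.0, 1.0, (size, size)), 2.0)
    texture /= texture.std()
    sd_map = np.full((size, size), _TEX_SCALE[BACKGROUND] * texture_sd)
    sd_map[tissue] = _TEX_SCALE[TISSUE] * texture_sd
    sd_map[lesion] = _TEX_SCALE[LESION] * texture_sd
    if kind == "malignant":
        sd_map[lesion] *= _MALIGNANT_TEX
    image = np.clip(image + texture * sd_map, 0.0, 1.0)

    return Phantom(
        image=image,
        truth_labels=labels,
        truth_mask=lesion,
        label=kind,
        seed=seed,
    )


def make_labeled_dataset(n_benign: int, n_malignant: int, seed: int = 0, size: int = 128):
    """Independent seeded phantoms, benign first then malignant."""
    if n_benign < 1 or n_malignant < 1:
        raise ValueError("need at least one phantom per class")
    child = np.random.SeedSequence(seed).generate_state(n_benign + n_malignant)
    out = []
    for i in range(n_benign):
        out.append(make_phantom(size=size, kind="benign", seed=int(child[i])))
    for i in range(n_malignant):
        out.append(make_phantom(size=size, kind="malignant", seed=int(child[n_benign + i])))
    return out


def noise_sweep_suite(phantoms, levels=(5.0, 7.0, 9.0), seed: int = 0, kind: str = "salt_pepper"):
    """Corrupt every phantom at every noise level; truth is kept unchanged.

    Salt-and-pepper corruption sets are nested across levels (a higher level
    corrupts the same pixels plus extra ones), so per-image accuracy is
    directly comparable between levels rather than confounded by independent
    pixel draws.  Gaussian noise falls back to independent per-level draws.
    Returns ``{level: [Phantom, ...]}``.
    """
    noise_seeds = np.random.SeedSequence(seed).generate_state(len(phantoms))
    out: dict[float, list[Phantom]] = {level: [] for level in levels}
    for ph, nseed in zip(phantoms, noise_seeds):
        rng = np.random.default_rng(int(nseed))
        n = ph.image.size
        perm = rng.permutation(n)
        vals = rng.integers(0, 2, size=n).astype(float)
        for level in levels:
            spec = NoiseSpec(kind, level, int(nseed))
            if kind == "salt_pepper":
                n_corrupt = int(round(level / 100.0 * n))
                flat = ph.image.ravel().copy()
                flat[perm[:n_corrupt]] = vals[:n_corrupt]
                noisy = flat.reshape(ph.image.shape)
            else:
                noisy = add_noise(ph.image, spec)
            out[level].append(
                Phantom(
                    image=noisy,
                    truth_labels=ph.truth_labels,
                    truth_mask=ph.truth_mask,
                    label=ph.label,
                    seed=ph.seed,
                    noise=spec,
                )
            )
    return out


def write_dataset(phantoms, out_dir, fmt: str = "png") -> Path:
    """Write phantom images plus a manifest CSV; returns the manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = out / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id", "image", "truth", "label", "seed", "noise_kind", "noise_level"])
        for i, ph in enumerate(phantoms):
            img_name = f"phantom_{i:04d}.{fmt}"
            truth_name = f"phantom_{i:04d}_truth.{fmt}"
            write_image(out / img_name, ph.image)
            write_image(out / truth_name, ph.truth_labels / 2.0)
            writer.writerow(
                [
                    i,
                    img_name,
                    truth_name,
                    ph.label,
                    ph.seed,
                    ph.noise.kind if ph.noise else "",
                    ph.noise.level if ph.noise else "",
                ]
            )
    return manifest
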