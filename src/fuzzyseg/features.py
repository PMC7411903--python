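"""Shape and gray-level-histogram texture descriptors of a segmented ROI.

Shape descriptors are driven by a 32-point radial profile of the ROI
boundary (normalized radial lengths, circularity, shape factor, boundary
gradient, central-position shift); texture descriptors are moments of the
masked intensity histogram.  The 16 numeric features of one ROI are
assembled into a flat record by :func:`feature_table`.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, fields

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import measure

__all__ = [
    "RoiMask",
    "RadialProfile",
    "ShapeFeatures",
    "TextureFeatures",
    "roi_mask_from_labels",
    "radial_profile",
    "shape_features",
    "gray_histogram",
    "texture_features",
    "feature_table",
    "FEATURE_COLUMNS",
]

logger = logging.getLogger(__name__)

N_RAYS = 32
MIN_ROI_PIXELS = 9


@dataclass
class RoiMask:
    mask: np.ndarray  # boolean
    centroid: tuple[float, float]  # (row, col)
    connected: bool = True


@dataclass
class RadialProfile:
    angles: np.ndarray  # N_RAYS angles in radians
    lengths: np.ndarray  # rl(r), pixels
    normalized: np.ndarray  # nrl(r) = rl / max(rl)
    star_shaped: bool = True


@dataclass
class ShapeFeatures:
    area: float
    perimeter: float
    circularity: float
    shape_factor: float
    nrl_mean: float
    nrl_sigma: float
    nrl_entropy: float
    ncps: float
    gradient: float


@dataclass
class TextureFeatures:
    mean: float
    std: float
    smoothness: float
    skewness: float
    uniformity: float
    entropy: float
    kurtosis: float


FEATURE_COLUMNS = [f.name for f in fields(ShapeFeatures)] + [
    f.name for f in fields(TextureFeatures)
]


def roi_mask_from_labels(label_map, roi_cluster: int) -> RoiMask:
    """Binary ROI mask of one cluster, reduced to its largest 8-connected component."""
    lm = np.asarray(label_map)
    raw = lm == roi_cluster
    if not raw.any():
        raise ValueError(f"cluster {roi_cluster} absent from label map")
    comp, n_comp = ndimage.label(raw, structure=np.ones((3, 3), dtype=int))
    sizes = ndimage.sum_labels(raw, comp, index=np.arange(1, n_comp + 1))
    largest = int(np.argmax(sizes)) + 1
    mask = comp == largest
    if mask.sum() < MIN_ROI_PIXELS:
        raise ValueError(
            f"largest component of cluster {roi_cluster} has "
            f"{int(mask.sum())} pixels (< {MIN_ROI_PIXELS})"
        )
    r, c = ndimage.center_of_mass(mask)
    return RoiMask(mask=mask, centroid=(float(r), float(c)), connected=n_comp == 1)


def _snap(x):
    """Round half away from the origin-consistent side (floor(x + 0.5)).

    Unlike banker's rounding this commutes with integer translation, which
    keeps the features translation-invariant.
    """
    return np.floor(np.asarray(x) + 0.5).astype(int)


def radial_profile(roi: RoiMask, n_rays: int = N_RAYS, step: float = 0.125) -> RadialProfile:
    """Centroid-to-boundary distances at ``n_rays`` equally spaced angles.

    Marches outward along each ray; the boundary crossing is the midpoint
    between the last inside and first outside sample.  If the centroid pixel
    itself falls outside the mask (non-star-shaped ROI), each ray instead
    takes the farthest inside sample and the ``star_shaped`` flag is cleared.
    """
    mask = roi.mask
    h, w = mask.shape
    cr, cc = roi.centroid
    angles = 2.0 * np.pi * np.arange(n_rays) / n_rays
    r_max = math.hypot(h, w)
    radii = np.arange(0.0, r_max + step, step)

    rows = np.clip(_snap(cr + np.outer(np.sin(angles), radii)), 0, h - 1)
    cols = np.clip(_snap(cc + np.outer(np.cos(angles), radii)), 0, w - 1)
    inside = mask[rows, cols]

    ci, cj = int(_snap(cr)), int(_snap(cc))
    centroid_inside = bool(0 <= ci < h and 0 <= cj < w and mask[ci, cj])
    lengths = np.empty(n_rays)
    if centroid_inside:
        # first inside->outside transition along each ray
        trans = inside[:, :-1] & ~inside[:, 1:]
        for i in range(n_rays):
            idx = np.nonzero(trans[i])[0]
            j = idx[0] if idx.size else inside.shape[1] - 2
            lengths[i] = 0.5 * (radii[j] + radii[j + 1])
    else:
        for i in range(n_rays):
            idx = np.nonzero(inside[i])[0]
            lengths[i] = radii[idx[-1]] + 0.5 * step if idx.size else step
    m = lengths.max()
    if m <= 0:
        raise ValueError("degenerate radial profile")
    return RadialProfile(angles, lengths, lengths / m, star_shaped=centroid_inside)


def _nrl_entropy(nrl: np.ndarray, bins: int = 10) -> float:
    hist, _ = np.histogram(nrl, bins=bins, range=(0.0, 1.0 + 1e-12))
    p = hist / hist.sum()
    nz = p[p > 0]
    return float(-(nz * np.log2(nz)).sum())


def shape_features(roi: RoiMask, profile: RadialProfile, image) -> ShapeFeatures:
    """Boundary-shape descriptor record (see :class:`ShapeFeatures`).

    Perimeter uses an arc-length weighted boundary estimate so that a
    rasterized disk scores circularity near zero and a square scores a shape
    factor near 16; raw boundary-pixel counts bias both systematically.
    """
    mask = roi.mask
    img = np.asarray(image, dtype=float)
    area = float(mask.sum())
    perim = float(measure.perimeter(mask, neighborhood=4))
    if area <= 0 or perim <= 0:
        raise ValueError("degenerate ROI")
    circ = 1.0 - 4.0 * math.pi * area / perim**2
    sf = perim**2 / area

    nrl = profile.normalized
    nrl_mean = float(nrl.mean())
    nrl_sigma = float(nrl.std())
    er = _nrl_entropy(nrl)

    # central position shift: centroid -> darkest pixel inside the ROI,
    # scaled by the equivalent radius
    masked = np.where(mask, img, np.inf)
    dark = np.unravel_index(np.argmin(masked), masked.shape)
    cr, cc = roi.centroid
    ncps = math.hypot(dark[0] - cr, dark[1] - cc) / math.sqrt(area / math.pi)

    # boundary gradient: intensity at the boundary minus 10 px inward, per ray
    h, w = mask.shape
    diffs = np.empty(len(profile.angles))
    for i, (theta, rl) in enumerate(zip(profile.angles, profile.lengths)):
        r_in = max(rl - 10.0, 0.0)
        br = min(max(int(_snap(cr + rl * math.sin(theta))), 0), h - 1)
        bc = min(max(int(_snap(cc + rl * math.cos(theta))), 0), w - 1)
        ir = min(max(int(_snap(cr + r_in * math.sin(theta))), 0), h - 1)
        ic = min(max(int(_snap(cc + r_in * math.cos(theta))), 0), w - 1)
        diffs[i] = img[br, bc] - img[ir, ic]
    return ShapeFeatures(area, perim, circ, sf, nrl_mean, nrl_sigma, er, float(ncps), float(diffs.mean()))


def gray_histogram(image, mask, levels: int = 256) -> np.ndarray:
    """Normalized ``levels``-bin histogram of the masked intensities in [0, 1]."""
    img = np.asarray(image, dtype=float)
    m = np.asarray(mask, dtype=bool)
    if not m.any():
        raise ValueError("empty mask")
    vals = np.clip(img[m], 0.0, 1.0)
    hist, _ = np.histogram(vals, bins=levels, range=(0.0, 1.0 + 1e-12))
    return hist / hist.sum()


def texture_features(h, levels=None) -> TextureFeatures:
    """Histogram-moment texture record.

    Moments are computed on level values rescaled to [0, 1]; skewness and
    kurtosis are raw third/fourth central moments (not standardized), entropy
    is Shannon entropy in bits, smoothness is ``1 - 1/(1 + var)``.
    """
    h = np.asarray(h, dtype=float)
    if abs(h.sum() - 1.0) > 1e-8:
        raise ValueError("histogram must be normalized to sum 1")
    L = h.size if levels is None else levels
    r = np.arange(h.size) / (L - 1) if L > 1 else np.zeros(h.size)
    mean = float((r * h).sum())
    var = float((((r - mean) ** 2) * h).sum())
    std = math.sqrt(var)
    smooth = 1.0 - 1.0 / (1.0 + var)
    skew = float((((r - mean) ** 3) * h).sum())
    kurt = float((((r - mean) ** 4) * h).sum())
    unif = float((h**2).sum())
    nz = h[h > 0]
    ent = float(-(nz * np.log2(nz)).sum())
    return TextureFeatures(mean, std, smooth, skew, unif, ent, kurt)


def extract_roi_features(image, label_map, roi_cluster: int, levels: int = 256):
    """Full 16-feature record for one ROI; returns a dict."""
    roi = roi_mask_from_labels(label_map, roi_cluster)
    prof = radial_profile(roi)
    sf = shape_features(roi, prof, image)
    tf = texture_features(gray_histogram(image, roi.mask, levels))
    rec = {f.name: getattr(sf, f.name) for f in fields(ShapeFeatures)}
    rec.update({f.name: getattr(tf, f.name) for f in fields(TextureFeatures)})
    return rec


def feature_table(images, label_maps, roi_clusters, ids=None, labels=None) -> pd.DataFrame:
    """One row of 16 features per ROI; failed ROIs are logged and skipped.

    Column order is fixed: ``id``, ``label`` (if given), then
    :data:`FEATURE_COLUMNS`.
    """
    if ids is None:
        ids = list(range(len(images)))
    rows = []
    for i, (img, lm, rc) in enumerate(zip(images, label_maps, roi_clusters)):
        try:
            rec = extract_roi_features(img, lm, rc)
        except ValueError as exc:
            logger.warning("skipping ROI %s: %s", ids[i], exc)
            continue
        row = {"id": ids[i]}
        if labels is not None:
            row["label"] = labels[i]
        row.update(rec)
        rows.append(row)
    cols = ["id"] + (["label"] if labels is not None else []) + FEATURE_COLUMNS
    return pd.DataFrame(rows, columns=cols)


def write_feature_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, float_format="%.17g")


def read_feature_table(path) -> pd.DataFrame:
    return pd.read_csv(path)
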