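"""End-to-end experiment drivers: segment, extract, classify, evaluate.

These functions connect the clustering, feature and classifier modules into
the four-stage pipeline (preprocess -> segment -> feature extraction ->
classification) and implement the noise-sweep segmentation benchmark.
"""

from __future__ import annotations

import logging
import time

import numpy as np
import pandas as pd

from fuzzyseg import clustering, features, fsvm, metrics

__all__ = [
    "SEGMENTATION_METHODS",
    "segment_image",
    "noise_sweep_table",
    "dataset_features",
    "stratified_split",
    "run_pipeline",
]

logger = logging.getLogger(__name__)

SEGMENTATION_METHODS = ("otsu", "fcm", "ifcm", "pfcm", "ipfcm")


def segment_image(
    image,
    method: str = "ipfcm",
    k: int = 3,
    p: float = 2.0,
    W: float = 1.0,
    sugeno_lambda: float = 2.0,
    seed: int = 0,
    tol: float = 1e-5,
    max_iter: int = 100,
):
    """Cluster pixel intensities into ``k`` classes; returns (labels, roi_cluster).

    Cluster indices are sorted by center intensity so the label map is
    ordered dark-to-bright; the ROI is the brightest cluster.  Otsu yields a
    binary map (roi_cluster = 1).
    """
    img = np.asarray(image, dtype=float)
    if method not in SEGMENTATION_METHODS:
        raise ValueError(
            f"unknown method {method!r}; choose from {', '.join(SEGMENTATION_METHODS)}"
        )
    if method == "otsu":
        thr = clustering.otsu_threshold(img)
        return (img > thr).astype(np.int64), 1

    data = img.reshape(-1, 1)
    if method == "fcm":
        part = clustering.fit_fcm(data, k, p=p, tol=tol, max_iter=max_iter, seed=seed)
    elif method == "ifcm":
        part = clustering.fit_ifcm(
            data, k, p=p, sugeno_lambda=sugeno_lambda, tol=tol, max_iter=max_iter, seed=seed
        )
    elif method == "pfcm":
        part, _ = clustering.fit_pfcm(data, k, p=p, W=W, tol=tol, max_iter=max_iter, seed=seed)
    else:
        part, _, _ = clustering.fit_ipfcm(
            data, k, p=p, W=W, sugeno_lambda=sugeno_lambda, tol=tol, max_iter=max_iter, seed=seed
        )
    raw = clustering.labels_from_partition(part)
    order = np.argsort(part.centers[:, 0], kind="stable")  # dark -> bright
    remap = np.empty(part.n_clusters, dtype=np.int64)
    remap[order] = np.arange(part.n_clusters)
    labels = remap[raw].reshape(img.shape)
    return labels, part.n_clusters - 1


def noise_sweep_table(
    phantom_groups: dict,
    methods=SEGMENTATION_METHODS,
    seed: int = 0,
    **seg_kwargs,
) -> pd.DataFrame:
    """Mean segmentation accuracy per method and noise level.

    ``phantom_groups`` maps noise level -> list of phantoms (level 0 may hold
    clean images).  Returns a DataFrame indexed by method with one column per
    level.
    """
    table = {}
    for method in methods:
        row = {}
        for level, group in phantom_groups.items():
            accs = []
            for ph in group:
                t0 = time.perf_counter()
                labels, _ = segment_image(ph.image, method=method, seed=seed, **seg_kwargs)
                accs.append(clustering.segmentation_accuracy(labels, ph.truth_labels))
                logger.info(
                    "segment method=%s level=%s seed=%s acc=%.4f (%.2fs)",
                    method, level, ph.seed, accs[-1], time.perf_counter() - t0,
                )
            row[level] = float(np.mean(accs))
        table[method] = row
    df = pd.DataFrame(table).T
    df.index.name = "method"
    return df


def dataset_features(
    phantoms,
    method: str = "ipfcm",
    seed: int = 0,
    **seg_kwargs,
) -> pd.DataFrame:
    """Segment every phantom and extract its 16-feature ROI record."""
    images, label_maps, roi_clusters, labels, ids = [], [], [], [], []
    for i, ph in enumerate(phantoms):
        lm, roi = segment_image(ph.image, method=method, seed=seed, **seg_kwargs)
        images.append(ph.image)
        label_maps.append(lm)
        roi_clusters.append(roi)
        labels.append(ph.label)
        ids.append(i)
    return features.feature_table(images, label_maps, roi_clusters, ids=ids, labels=labels)


def stratified_split(labels, test_frac: float = 0.3, seed: int = 0):
    """Seeded stratified train/test index split."""
    z = np.asarray(labels)
    rng = np.random.default_rng(seed)
    train_idx, test_idx = [], []
    for cls in np.unique(z):
        idx = np.nonzero(z == cls)[0]
        perm = rng.permutation(idx)
        n_test = max(1, int(round(test_frac * idx.size)))
        test_idx.extend(perm[:n_test])
        train_idx.extend(perm[n_test:])
    return np.sort(np.asarray(train_idx)), np.sort(np.asarray(test_idx))


def run_pipeline(
    phantoms,
    method: str = "ipfcm",
    C: float = 10.0,
    sigma: float = 4.0,
    weighting: bool = True,
    test_frac: float = 0.3,
    split_seed: int = 0,
    seg_seed: int = 0,
    feature_df: pd.DataFrame | None = None,
    **seg_kwargs,
) -> dict:
    """Full pipeline on a labeled phantom set; returns a metric report dict.

    Pass a precomputed ``feature_df`` to reuse segmentations across split
    seeds.  Malignant maps to +1, benign to -1.  The default kernel width is
    wider than the classifier-level default because the 16-dimensional
    standardized feature vectors sit several units apart on average.
    """
    if feature_df is None:
        feature_df = dataset_features(phantoms, method=method, seed=seg_seed, **seg_kwargs)
    if feature_df["label"].nunique() < 2:
        raise ValueError("pipeline needs both classes among extracted ROIs")
    X = feature_df[features.FEATURE_COLUMNS].to_numpy(dtype=float)
    z = np.where(feature_df["label"].to_numpy() == "malignant", 1, -1)

    train_idx, test_idx = stratified_split(z, test_frac=test_frac, seed=split_seed)
    preds, model = fsvm.fit_predict(
        X[train_idx], z[train_idx], X[test_idx], C=C, sigma=sigma, weighting=weighting
    )
    scores = fsvm.decision_value(model, X[test_idx])
    counts = metrics.confusion_counts(z[test_idx], preds)
    report = metrics.binary_metrics(counts)
    try:
        _, _, auc = metrics.roc_auc(scores, z[test_idx])
    except ValueError:
        auc = float("nan")
    report["auc"] = auc
    report["n_train"] = int(train_idx.size)
    report["n_test"] = int(test_idx.size)
    report["method"] = method
    report["weighting"] = weighting
    return report
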