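"""Fuzzy clustering algorithms and segmentation scoring.

Four alternating-update clustering algorithms built from shared primitives:

* FCM — probabilistic memberships, rows sum to one.
* PFCM — possibilistic typicalities, per-cluster distance scales, no
  sum-to-one constraint; robust to outliers.
* IFCM — FCM whose memberships are boosted by a hesitation degree derived
  from the Sugeno negation before the center update.
* IPFCM — the hybrid: possibilistic typicalities boosted by their hesitation
  degree before center updates.

Plus an Otsu threshold baseline, hard-label extraction and a
permutation-invariant segmentation accuracy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

__all__ = [
    "FuzzyPartition",
    "PossibilisticState",
    "IntuitionisticParams",
    "squared_distances",
    "fcm_memberships",
    "weighted_centers",
    "fcm_objective",
    "fit_fcm",
    "pcm_scales",
    "pcm_typicality",
    "fit_pfcm",
    "sugeno_hesitation",
    "star_membership",
    "fit_ifcm",
    "ipfcm_objective",
    "fit_ipfcm",
    "otsu_threshold",
    "labels_from_partition",
    "segmentation_accuracy",
]


@dataclass
class FuzzyPartition:
    """State of a fuzzy clustering run.

    ``memberships`` is the governing N-by-k matrix of the algorithm that
    produced it: probabilistic memberships for FCM, star memberships
    (membership + hesitation) for IFCM, typicalities for PFCM and boosted
    typicalities for IPFCM.  ``objective_trace`` records the objective value
    once per iteration.
    """

    memberships: np.ndarray
    centers: np.ndarray
    fuzzifier: float
    iterations_run: int
    converged: bool
    objective_trace: list[float] = field(default_factory=list)

    @property
    def n_clusters(self) -> int:
        return self.centers.shape[0]


@dataclass
class PossibilisticState:
    """Typicality matrix plus the per-cluster distance scales."""

    typicalities: np.ndarray
    scales: np.ndarray
    weight: float = 1.0


@dataclass
class IntuitionisticParams:
    """Per-element intuitionistic decomposition u + nu + pi = 1."""

    sugeno_lambda: float
    nonmemberships: np.ndarray
    hesitations: np.ndarray
    star_memberships: np.ndarray


def _as_points(data: np.ndarray) -> np.ndarray:
    pts = np.asarray(data, dtype=float)
    if pts.ndim == 1:
        pts = pts[:, None]
    if pts.ndim != 2 or pts.shape[0] < 1:
        raise ValueError("data must be a non-empty 1-D or 2-D array")
    if not np.all(np.isfinite(pts)):
        raise ValueError("data contains non-finite values")
    return pts


def squared_distances(data: np.ndarray, centers: np.ndarray) -> np.ndarray:
    """Pairwise squared Euclidean distances between points and centers.

    Returns an N-by-k matrix whose (l, m) entry is ``||x_l - v_m||**2``.
    """
    pts = _as_points(data)
    ctr = np.asarray(centers, dtype=float)
    if ctr.ndim == 1:
        ctr = ctr[:, None]
    if not np.all(np.isfinite(ctr)):
        raise ValueError("centers contain non-finite values")
    if ctr.shape[1] != pts.shape[1]:
        raise ValueError(
            f"dimension mismatch: data has {pts.shape[1]} features, "
            f"centers have {ctr.shape[1]}"
        )
    diff = pts[:, None, :] - ctr[None, :, :]
    return np.einsum("lmd,lmd->lm", diff, diff)


def fcm_memberships(sq_dists: np.ndarray, p: float) -> np.ndarray:
    """Probabilistic membership update; rows sum to one.

    u_lm = 1 / sum_q (d_lm^2 / d_lq^2)^(1/(p-1)).  A point at zero distance
    from one or more centers gets full membership there, split equally on
    ties.
    """
    if p <= 1:
        raise ValueError("fuzzifier p must be > 1")
    d2 = np.asarray(sq_dists, dtype=float)
    if d2.ndim != 2 or d2.shape[1] < 1:
        raise ValueError("sq_dists must be an N-by-k matrix")
    expo = 1.0 / (p - 1.0)
    zero = d2 <= 0.0
    any_zero = zero.any(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        inv = d2 ** (-expo)
        u = inv / inv.sum(axis=1, keepdims=True)
    if any_zero.any():
        rows = np.nonzero(any_zero)[0]
        u[rows] = 0.0
        counts = zero[rows].sum(axis=1)
        u[rows] = zero[rows] / counts[:, None]
    return u


def weighted_centers(memberships: np.ndarray, data: np.ndarray, p: float) -> np.ndarray:
    """Center update: v_m = sum_l u_lm^p x_l / sum_l u_lm^p."""
    pts = _as_points(data)
    u = np.asarray(memberships, dtype=float)
    w = u**p
    denom = w.sum(axis=0)
    empty = np.nonzero(denom <= 0.0)[0]
    if empty.size:
        raise ValueError(f"cluster {empty[0]} has zero total membership weight")
    return (w.T @ pts) / denom[:, None]


def fcm_objective(memberships: np.ndarray, sq_dists: np.ndarray, p: float) -> float:
    """FCM objective sum_m sum_l u_lm^p d_lm^2."""
    u = np.asarray(memberships, dtype=float)
    d2 = np.asarray(sq_dists, dtype=float)
    if u.shape != d2.shape:
        raise ValueError("memberships and sq_dists shapes disagree")
    return float(np.sum(u**p * d2))


def sugeno_hesitation(u, sugeno_lambda: float):
    """Nonmembership and hesitation via the Sugeno negation.

    nu = (1 - u) / (1 + lambda_s * u); pi = 1 - u - nu.  The identity
    u + nu + pi = 1 holds exactly by construction and pi >= 0 for
    lambda_s >= 0.
    """
    if sugeno_lambda < 0:
        raise ValueError("sugeno_lambda must be >= 0")
    u = np.asarray(u, dtype=float)
    if np.any(u < 0) or np.any(u > 1):
        raise ValueError("memberships must lie in [0, 1]")
    nu = (1.0 - u) / (1.0 + sugeno_lambda * u)
    pi = 1.0 - u - nu
    return nu, pi


def star_membership(u, pi):
    """Intuitionistic star membership u* = u + pi."""
    return np.asarray(u, dtype=float) + np.asarray(pi, dtype=float)


def _init_centers(pts: np.ndarray, k: int, seed: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    idx = rng.choice(pts.shape[0], size=k, replace=False)
    return pts[idx].copy()


def _fit_star_fcm(data, k, p, sugeno_lambda, tol, max_iter, seed):
    """Shared FCM/IFCM loop.

    Each iteration: distances -> probabilistic memberships -> hesitation
    boost (identity when sugeno_lambda == 0) -> center update with the
    boosted matrix.  Convergence on the max absolute change of the boosted
    matrix.
    """
    pts = _as_points(data)
    n = pts.shape[0]
    if k > n:
        raise ValueError(f"k={k} exceeds number of points N={n}")
    if np.all(pts == pts[0]):
        warnings.warn("degenerate data: all points identical; returning a single center")
        u = np.ones((n, 1))
        part = FuzzyPartition(u, pts[:1].copy(), p, 0, True, [0.0])
        return part, IntuitionisticParams(sugeno_lambda, 1.0 - u, np.zeros_like(u), u)

    centers = _init_centers(pts, k, seed)
    prev_star = None
    trace: list[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        d2 = squared_distances(pts, centers)
        u = fcm_memberships(d2, p)
        nu, pi = sugeno_hesitation(u, sugeno_lambda)
        u_star = u + pi
        trace.append(fcm_objective(u_star, d2, p))
        centers = weighted_centers(u_star, pts, p)
        if prev_star is not None and np.max(np.abs(u_star - prev_star)) < tol:
            converged = True
            break
        prev_star = u_star
    part = FuzzyPartition(u_star, centers, p, it, converged, trace)
    return part, IntuitionisticParams(sugeno_lambda, nu, pi, u_star)


def fit_fcm(data, k, p=2.0, tol=1e-5, max_iter=100, seed=0) -> FuzzyPartition:
    """Fuzzy c-means from a seeded random center initialization.

    Alternates :func:`fcm_memberships` and :func:`weighted_centers` until the
    membership matrix changes by less than ``tol`` (max absolute entry) or
    ``max_iter`` iterations.  Deterministic given ``seed``.
    """
    part, _ = _fit_star_fcm(data, k, p, 0.0, tol, max_iter, seed)
    return part


def fit_ifcm(data, k, p=2.0, sugeno_lambda=2.0, tol=1e-5, max_iter=100, seed=0):
    """Intuitionistic FCM: centers updated with hesitation-boosted memberships.

    With ``sugeno_lambda == 0`` the boost is the identity and the run is
    bitwise identical to :func:`fit_fcm` with the same seed.
    """
    part, _ = _fit_star_fcm(data, k, p, sugeno_lambda, tol, max_iter, seed)
    return part


def pcm_scales(memberships, sq_dists, p, W=1.0) -> np.ndarray:
    """Per-cluster distance scales lambda_m = W * sum u^p d^2 / sum u^p."""
    u = np.asarray(memberships, dtype=float)
    d2 = np.asarray(sq_dists, dtype=float)
    w = u**p
    denom = w.sum(axis=0)
    if np.any(denom <= 0.0):
        raise ValueError("zero membership mass in a cluster; scales undefined")
    return W * (w * d2).sum(axis=0) / denom


def pcm_typicality(sq_dists, scales, p) -> np.ndarray:
    """Possibilistic typicality u = 1 / (1 + (d^2/lambda)^(1/(p-1))).

    Each entry is the exact minimizer of u^p d^2 + lambda (1-u)^p over
    u in [0, 1]; columns are independent (no sum-to-one constraint).
    """
    if p <= 1:
        raise ValueError("fuzzifier p must be > 1")
    lam = np.asarray(scales, dtype=float)
    if np.any(lam <= 0):
        raise ValueError("scales must be positive")
    d2 = np.asarray(sq_dists, dtype=float)
    return 1.0 / (1.0 + (d2 / lam) ** (1.0 / (p - 1.0)))


def ipfcm_objective(star_memberships, sq_dists, scales, p) -> float:
    """Hybrid objective sum u*^p d^2 + sum_m lambda_m sum_l (1 - u*)^p."""
    us = np.asarray(star_memberships, dtype=float)
    d2 = np.asarray(sq_dists, dtype=float)
    if us.shape != d2.shape:
        raise ValueError("star_memberships and sq_dists shapes disagree")
    lam = np.asarray(scales, dtype=float)
    return float(np.sum(us**p * d2) + np.sum(lam * ((1.0 - us) ** p).sum(axis=0)))


def _fit_possibilistic(data, k, p, W, sugeno_lambda, tol, max_iter, seed):
    """Shared PFCM/IPFCM machinery.

    Initialization runs FCM to convergence; the hesitation boost is applied
    once to the converged FCM memberships, entering the distance scales
    (boosted numerator over plain denominator) and the starting centers.
    The loop is then an exact alternating minimization of
    :func:`ipfcm_objective` with the scales held fixed — each typicality
    update is the per-element minimizer and each center update the weighted
    mean — so the objective trace is non-increasing.  With
    ``sugeno_lambda == 0`` the boost is the identity and the run reduces
    bitwise to plain PFCM with scales from the converged FCM memberships.
    """
    pts = _as_points(data)
    fcm_part = fit_fcm(pts, k, p=p, tol=tol, max_iter=max_iter, seed=seed)
    if fcm_part.n_clusters < k:  # degenerate data collapsed to one center
        t = fcm_part.memberships
        state = PossibilisticState(t, np.ones(1), W)
        ipar = IntuitionisticParams(sugeno_lambda, 1.0 - t, np.zeros_like(t), t)
        return fcm_part, state, ipar

    d2 = squared_distances(pts, fcm_part.centers)
    u = fcm_part.memberships
    nu0, pi0 = sugeno_hesitation(u, sugeno_lambda)
    u_star0 = u + pi0
    denom = (u**p).sum(axis=0)
    scales = W * (u_star0**p * d2).sum(axis=0) / denom
    if np.any(scales <= 0):
        raise ValueError("non-positive distance scale from initialization")

    centers = weighted_centers(u_star0, pts, p)
    prev = None
    trace: list[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        d2 = squared_distances(pts, centers)
        t = pcm_typicality(d2, scales, p)
        trace.append(ipfcm_objective(t, d2, scales, p))
        centers = weighted_centers(t, pts, p)
        if prev is not None and np.max(np.abs(t - prev)) < tol:
            converged = True
            break
        prev = t
    part = FuzzyPartition(t, centers, p, it, converged, trace)
    state = PossibilisticState(t, scales, W)
    ipar = IntuitionisticParams(sugeno_lambda, nu0, pi0, u_star0)
    return part, state, ipar


def fit_pfcm(data, k, p=2.0, W=1.0, tol=1e-5, max_iter=100, seed=0):
    """Possibilistic FCM: FCM init, fixed scales, typicality/center alternation.

    Returns ``(FuzzyPartition, PossibilisticState)``; the partition's
    membership matrix holds the typicalities.
    """
    part, state, _ = _fit_possibilistic(data, k, p, W, 0.0, tol, max_iter, seed)
    return part, state


def fit_ipfcm(data, k, p=2.0, W=1.0, sugeno_lambda=2.0, tol=1e-5, max_iter=100, seed=0):
    """Hybrid intuitionistic-possibilistic FCM.

    The converged FCM memberships are boosted once by their Sugeno
    hesitation degree; the boosted matrix sets the starting centers and
    inflates the distance scales, after which typicalities and centers
    alternate exactly as in PFCM.  ``sugeno_lambda == 0`` reduces bitwise to
    :func:`fit_pfcm`.  Returns ``(FuzzyPartition, PossibilisticState,
    IntuitionisticParams)``.
    """
    return _fit_possibilistic(data, k, p, W, sugeno_lambda, tol, max_iter, seed)


def otsu_threshold(image, levels: int = 256) -> float:
    """Between-class-variance-maximizing threshold over a histogram.

    Builds a ``levels``-bin histogram over the image's value range and scans
    every cut point; returns the intensity of the lowest maximizing cut (the
    upper edge of the last bin of the lower class).
    """
    vals = np.asarray(image, dtype=float).ravel()
    vmin, vmax = vals.min(), vals.max()
    if vmin == vmax:
        raise ValueError("degenerate histogram: image is constant")
    hist, edges = np.histogram(vals, bins=levels, range=(vmin, vmax))
    w = hist / hist.sum()
    centers = 0.5 * (edges[:-1] + edges[1:])
    w0 = np.cumsum(w)[:-1]
    w1 = 1.0 - w0
    mu = np.cumsum(w * centers)
    mu_total = mu[-1]
    mu0 = np.divide(mu[:-1], w0, out=np.zeros_like(w0), where=w0 > 0)
    mu1 = np.divide(mu_total - mu[:-1], w1, out=np.zeros_like(w1), where=w1 > 0)
    sigma_b = w0 * w1 * (mu0 - mu1) ** 2
    # lowest cut within roundoff of the maximum (ties -> lowest threshold;
    # empty bins between modes make sigma_b exactly flat up to float noise)
    peak = sigma_b.max()
    best = int(np.nonzero(sigma_b >= peak - 1e-12 * max(peak, 1.0))[0][0])
    return float(edges[best + 1])


def labels_from_partition(partition: FuzzyPartition) -> np.ndarray:
    """Hard labels by per-point argmax membership; ties take the lowest index."""
    return np.argmax(partition.memberships, axis=1)


def segmentation_accuracy(labels, truth) -> float:
    """Best-permutation pixel agreement between two label maps, in [0, 1].

    The score is the fraction of pixels agreeing under the best injective
    relabeling of predicted clusters onto truth clusters, so it is invariant
    to label permutations.  Both maps must use at most 8 distinct labels.
    """
    a = np.asarray(labels)
    b = np.asarray(truth)
    if a.shape != b.shape:
        raise ValueError("label maps must have the same shape")
    la, ia = np.unique(a, return_inverse=True)
    lb, ib = np.unique(b, return_inverse=True)
    if la.size > 8 or lb.size > 8:
        raise ValueError("segmentation_accuracy supports at most 8 labels")
    k = max(la.size, lb.size)
    conf = np.zeros((k, k), dtype=np.int64)
    np.add.at(conf, (ia.ravel(), ib.ravel()), 1)
    rows, cols = linear_sum_assignment(conf, maximize=True)
    return float(conf[rows, cols].sum()) / a.size
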