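"""Fuzzy-weighted support vector machine with a Gaussian kernel.

Per-sample fuzzy weights s_m scale the box constraint of the dual problem
(0 <= beta_m <= s_m * C), shrinking the influence of samples far from their
class center.  The dual is solved by SMO-style pairwise coordinate descent
with maximal-violating-pair working-set selection; the solver is
deterministic given the input order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

__all__ = [
    "FSVMModel",
    "gaussian_kernel",
    "kernel_matrix",
    "class_center_memberships",
    "solve_fsvm_dual",
    "decision_value",
    "fit_predict",
]


def gaussian_kernel(y1, y2, sigma: float) -> float:
    """exp(-||y1 - y2||^2 / (2 sigma^2))."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    a = np.asarray(y1, dtype=float)
    b = np.asarray(y2, dtype=float)
    if a.shape != b.shape:
        raise ValueError("kernel arguments must have equal dimension")
    d2 = float(((a - b) ** 2).sum())
    return float(np.exp(-d2 / (2.0 * sigma**2)))


def kernel_matrix(X, Y, sigma: float) -> np.ndarray:
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    d2 = ((X[:, None, :] - Y[None, :, :]) ** 2).sum(axis=2)
    return np.exp(-d2 / (2.0 * sigma**2))


@dataclass
class FSVMModel:
    """Trained fuzzy SVM: support coefficients, bias and kernel parameters."""

    support_vectors: np.ndarray
    support_coef: np.ndarray  # beta_m * z_m for the support vectors
    bias: float
    sigma: float
    C: float
    kkt_residual: float
    mean_: np.ndarray | None = None  # standardization constants, if used
    scale_: np.ndarray | None = None

    def to_json(self) -> str:
        payload = {
            "support_vectors": self.support_vectors.tolist(),
            "support_coef": self.support_coef.tolist(),
            "bias": self.bias,
            "sigma": self.sigma,
            "C": self.C,
            "kkt_residual": self.kkt_residual,
            "mean": None if self.mean_ is None else self.mean_.tolist(),
            "scale": None if self.scale_ is None else self.scale_.tolist(),
        }
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "FSVMModel":
        d = json.loads(text)
        return cls(
            support_vectors=np.asarray(d["support_vectors"], dtype=float),
            support_coef=np.asarray(d["support_coef"], dtype=float),
            bias=float(d["bias"]),
            sigma=float(d["sigma"]),
            C=float(d["C"]),
            kkt_residual=float(d["kkt_residual"]),
            mean_=None if d["mean"] is None else np.asarray(d["mean"], dtype=float),
            scale_=None if d["scale"] is None else np.asarray(d["scale"], dtype=float),
        )


def class_center_memberships(inputs, labels, delta: float = 1e-6) -> np.ndarray:
    """Fuzzy weights decaying linearly with distance from the class center.

    s_m = 1 - d_m / (r + delta) with r the largest in-class distance to the
    class mean, so s in (0, 1]; a single-point class gets weight 1.
    """
    X = np.atleast_2d(np.asarray(inputs, dtype=float))
    z = np.asarray(labels)
    s = np.ones(X.shape[0])
    for cls in np.unique(z):
        idx = np.nonzero(z == cls)[0]
        center = X[idx].mean(axis=0)
        d = np.sqrt(((X[idx] - center) ** 2).sum(axis=1))
        r = d.max()
        if r > 0:
            s[idx] = 1.0 - d / (r + delta)
    return s


def solve_fsvm_dual(
    X,
    z,
    fuzzy_weights=None,
    C: float = 10.0,
    sigma: float = 1.0,
    tol: float = 1e-8,
    max_pairs: int = 100_000,
) -> FSVMModel:
    """Solve the fuzzy-SVM dual by maximal-violating-pair coordinate descent.

    Maximizes ``sum beta - 1/2 sum beta_m beta_n z_m z_n K(y_m, y_n)``
    subject to ``sum beta z = 0`` and ``0 <= beta_m <= s_m C``.  Raises if
    the KKT residual has not reached ``1e-6`` within ``max_pairs`` updates.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    z = np.asarray(z, dtype=float)
    n = X.shape[0]
    if set(np.unique(z)) - {-1.0, 1.0}:
        raise ValueError("labels must be in {-1, +1}")
    if np.unique(z).size < 2:
        raise ValueError("both classes must be present")
    s = np.ones(n) if fuzzy_weights is None else np.asarray(fuzzy_weights, dtype=float)
    if np.any(s <= 0):
        raise ValueError("fuzzy weights must be positive")
    box = s * C

    K = kernel_matrix(X, X, sigma)
    Q = (z[:, None] * z[None, :]) * K
    beta = np.zeros(n)
    grad = -np.ones(n)  # gradient of 1/2 b'Qb - sum(b)

    residual = np.inf
    for _ in range(max_pairs):
        zg = -z * grad
        up = ((z > 0) & (beta < box - 1e-12)) | ((z < 0) & (beta > 1e-12))
        low = ((z > 0) & (beta > 1e-12)) | ((z < 0) & (beta < box - 1e-12))
        if not up.any() or not low.any():
            residual = 0.0
            break
        i = int(np.argmax(np.where(up, zg, -np.inf)))
        j = int(np.argmin(np.where(low, zg, np.inf)))
        residual = zg[i] - zg[j]
        if residual < tol:
            break
        quad = max(Q[i, i] + Q[j, j] - 2.0 * z[i] * z[j] * Q[i, j], 1e-12)
        lam = residual / quad
        lam = min(lam, box[i] - beta[i] if z[i] > 0 else beta[i])
        lam = min(lam, beta[j] if z[j] > 0 else box[j] - beta[j])
        dbi = z[i] * lam
        dbj = -z[j] * lam
        beta[i] += dbi
        beta[j] += dbj
        grad += Q[:, i] * dbi + Q[:, j] * dbj

    if residual > 1e-6:
        raise RuntimeError(
            f"FSVM solver did not converge: KKT residual {residual:.3e} after "
            f"{max_pairs} pair updates"
        )

    margin = (beta > 1e-8) & (beta < box - 1e-8)
    f_no_bias = K @ (beta * z)
    if margin.any():
        bias = float(np.mean(z[margin] - f_no_bias[margin]))
    else:
        zg = -z * grad
        up = ((z > 0) & (beta < box - 1e-12)) | ((z < 0) & (beta > 1e-12))
        low = ((z > 0) & (beta > 1e-12)) | ((z < 0) & (beta < box - 1e-12))
        hi = zg[up].max() if up.any() else 0.0
        lo = zg[low].min() if low.any() else 0.0
        bias = float((hi + lo) / 2.0)

    sv = beta > 1e-10
    return FSVMModel(
        support_vectors=X[sv],
        support_coef=(beta * z)[sv],
        bias=bias,
        sigma=sigma,
        C=C,
        kkt_residual=float(max(residual, 0.0)),
    )


def decision_value(model: FSVMModel, y) -> np.ndarray | float:
    """Decision function sum_m beta_m z_m K(y_m, y) + bias."""
    Y = np.asarray(y, dtype=float)
    scalar = Y.ndim == 1
    Y = np.atleast_2d(Y)
    if Y.shape[1] != model.support_vectors.shape[1]:
        raise ValueError("dimension mismatch with the trained model")
    if model.mean_ is not None:
        Y = (Y - model.mean_) / model.scale_
    K = kernel_matrix(Y, model.support_vectors, model.sigma)
    vals = K @ model.support_coef + model.bias
    return float(vals[0]) if scalar else vals


def fit_predict(
    train_X,
    train_z,
    test_X,
    C: float = 10.0,
    sigma: float = 1.0,
    weighting: bool = True,
):
    """Standardize, weight, train, and predict labels for the test set.

    Features are standardized using training statistics; fuzzy weights come
    from :func:`class_center_memberships` when ``weighting`` is on, else all
    ones (plain SVM).  Ties (decision value exactly 0) predict +1.
    """
    Xtr = np.atleast_2d(np.asarray(train_X, dtype=float))
    z = np.asarray(train_z, dtype=float)
    mean = Xtr.mean(axis=0)
    scale = Xtr.std(axis=0)
    scale[scale == 0] = 1.0
    Xs = (Xtr - mean) / scale
    s = class_center_memberships(Xs, z) if weighting else None
    model = solve_fsvm_dual(Xs, z, s, C=C, sigma=sigma)
    model.mean_ = mean
    model.scale_ = scale
    vals = decision_value(model, np.atleast_2d(np.asarray(test_X, dtype=float)))
    preds = np.where(vals >= 0, 1, -1)
    return preds, model
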