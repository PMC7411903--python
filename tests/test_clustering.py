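import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fuzzyseg import clustering as cl


# ---------------------------------------------------------------- oracles


def grid_min_fcm_row(d2_row, p, step=1e-4):
    """Brute-force minimizer of sum u^p d^2 over the 2-simplex (k=2 only)."""
    u1 = np.arange(0.0, 1.0 + step, step)
    obj = u1**p * d2_row[0] + (1.0 - u1) ** p * d2_row[1]
    best = u1[np.argmin(obj)]
    return np.array([best, 1.0 - best])

def grid_min_typicality(d2, lam, p, step=1e-4):
    """Brute-force minimizer of u^p d^2 + lam (1-u)^p over [0, 1]."""
    u = np.arange(0.0, 1.0 + step, step)
    return u[np.argmin(u**p * d2 + lam * (1.0 - u) ** p)]

def otsu_exhaustive(values, levels=256):
    """Independent between-class-variance scan over every histogram cut."""
    vals = np.asarray(values, dtype=float).ravel()
    hist, edges = np.histogram(vals, bins=levels, range=(vals.min(), vals.max()))
    centers = 0.5 * (edges[:-1] + edges[1:])
    total = hist.sum()
    sigmas = []
    for cut in range(levels - 1):
        n0 = hist[: cut + 1].sum()
        n1 = total - n0
        if n0 == 0 or n1 == 0:
            sigmas.append(0.0)
        else:
            mu0 = (hist[: cut + 1] * centers[: cut + 1]).sum() / n0
            mu1 = (hist[cut + 1 :] * centers[cut + 1 :]).sum() / n1
            sigmas.append((n0 / total) * (n1 / total) * (mu0 - mu1) ** 2)
    sigmas = np.asarray(sigmas)
    peak = sigmas.max()
    best_cut = int(np.nonzero(sigmas >= peak - 1e-12 * max(peak, 1.0))[0][0])
    return edges[best_cut + 1]

def accuracy_brute(labels, truth):
    a = np.asarray(labels).ravel()
    b = np.asarray(truth).ravel()
    la, ia = np.unique(a, return_inverse=True)
    lb, ib = np.unique(b, return_inverse=True)
    k = max(la.size, lb.size)
    conf = np.zeros((k, k), dtype=int)
    np.add.at(conf, (ia, ib), 1)
    return max(
        sum(conf[i, perm[i]] for i in range(k))
        for perm in itertools.permutations(range(k))
    ) / a.size


# ---------------------------------------------------------------- distances


def test_squared_distances_point_at_center():
    assert cl.squared_distances([0.5], [0.5])[0, 0] == 0.0

def test_squared_distances_two_centers():
    np.testing.assert_allclose(cl.squared_distances([0.0], [1.0, 2.0]), [[1.0, 4.0]])

def test_squared_distances_345():
    d2 = cl.squared_distances(np.array([[3.0, 4.0]]), np.array([[0.0, 0.0]]))
    assert d2[0, 0] == 25.0

def test_squared_distances_dim_mismatch():
    with pytest.raises(ValueError, match="dimension mismatch"):
        cl.squared_distances(np.ones((3, 2)), np.ones((2, 3)))


# ---------------------------------------------------------------- memberships


def test_fcm_memberships_zero_distance_singularity():
    u = cl.fcm_memberships(np.array([[0.0, 1.0]]), p=2.0)
    np.testing.assert_array_equal(u, [[1.0, 0.0]])

def test_fcm_memberships_equidistant():
    for p in (1.5, 2.0, 3.0):
        u = cl.fcm_memberships(np.array([[0.7, 0.7]]), p=p)
        np.testing.assert_allclose(u, [[0.5, 0.5]])

def test_fcm_memberships_derived_value():
    u = cl.fcm_memberships(np.array([[1.0, 4.0]]), p=2.0)
    np.testing.assert_allclose(u, [[0.8, 0.2]])

def test_fcm_memberships_matches_grid_oracle():
    rng = np.random.default_rng(0)
    for _ in range(25):
        d2 = rng.uniform(0.05, 5.0, size=2)
        p = rng.uniform(1.5, 3.0)
        u = cl.fcm_memberships(d2[None, :], p)[0]
        np.testing.assert_allclose(u, grid_min_fcm_row(d2, p), atol=1e-3)

def test_fcm_memberships_bad_fuzzifier():
    with pytest.raises(ValueError):
        cl.fcm_memberships(np.ones((1, 2)), p=1.0)

def test_fcm_zero_tie_split():
    u = cl.fcm_memberships(np.array([[0.0, 0.0, 2.0]]), p=2.0)
    np.testing.assert_array_equal(u, [[0.5, 0.5, 0.0]])

@settings(max_examples=50, deadline=None)
@given(st.integers(0, 2**32 - 1))
def test_fcm_membership_rows_sum_to_one(seed):
    rng = np.random.default_rng(seed)
    d2 = rng.uniform(1e-3, 10.0, size=(7, rng.integers(2, 6)))
    u = cl.fcm_memberships(d2, rng.uniform(1.2, 4.0))
    np.testing.assert_allclose(u.sum(axis=1), 1.0, atol=1e-9)
    assert np.all((u >= 0) & (u <= 1))


# ---------------------------------------------------------------- centers


def test_weighted_centers_crisp():
    x = np.array([0.0, 1.0, 10.0, 12.0])
    u = np.array([[1, 0], [1, 0], [0, 1], [0, 1]], dtype=float)
    v = cl.weighted_centers(u, x, p=2.0)
    np.testing.assert_allclose(v[:, 0], [0.5, 11.0])

def test_weighted_centers_uniform():
    v = cl.weighted_centers(np.ones((2, 1)), np.array([0.0, 1.0]), p=2.0)
    assert v[0, 0] == 0.5

def test_weighted_centers_derived():
    u = np.array([[0.8], [0.5], [0.2]])
    v = cl.weighted_centers(u, np.array([0.0, 1.0, 2.0]), p=2.0)
    np.testing.assert_allclose(v[0, 0], 0.33 / 0.93)
    # independent 1-D grid check of the weighted-mean minimizer
    grid = np.linspace(0.0, 2.0, 20001)
    obj = [(u[:, 0] ** 2 * (np.array([0.0, 1.0, 2.0]) - g) ** 2).sum() for g in grid]
    assert abs(grid[np.argmin(obj)] - v[0, 0]) < 1e-3

def test_weighted_centers_empty_cluster():
    u = np.array([[1.0, 0.0], [1.0, 0.0]])
    with pytest.raises(ValueError, match="cluster 1"):
        cl.weighted_centers(u, np.array([0.0, 1.0]), p=2.0)


# ---------------------------------------------------------------- objective


def test_fcm_objective_zero():
    assert cl.fcm_objective(np.eye(2), np.zeros((2, 2)), 2.0) == 0.0

def test_fcm_objective_half():
    assert cl.fcm_objective(np.array([[0.5, 0.5]]), np.array([[1.0, 1.0]]), 2.0) == 0.5

def test_fcm_objective_derived():
    val = cl.fcm_objective(np.array([[0.8, 0.2]]), np.array([[1.0, 4.0]]), 2.0)
    np.testing.assert_allclose(val, 0.8)


# ---------------------------------------------------------------- fit_fcm


def test_fit_fcm_two_blobs(two_blob_data):
    part = cl.fit_fcm(two_blob_data, 2, seed=1)
    assert part.converged
    np.testing.assert_allclose(np.sort(part.centers[:, 0]), [0.1, 0.9], atol=1e-3)

def test_fit_fcm_k1_mean(two_blob_data):
    part = cl.fit_fcm(two_blob_data, 1, seed=0)
    np.testing.assert_allclose(part.centers[0, 0], two_blob_data.mean())
    np.testing.assert_array_equal(part.memberships, np.ones((6, 1)))

def test_fit_fcm_deterministic(two_blob_data):
    a = cl.fit_fcm(two_blob_data, 2, seed=9)
    b = cl.fit_fcm(two_blob_data, 2, seed=9)
    np.testing.assert_array_equal(a.memberships, b.memberships)
    np.testing.assert_array_equal(a.centers, b.centers)

def test_fit_fcm_k_too_large():
    with pytest.raises(ValueError, match="exceeds"):
        cl.fit_fcm(np.array([0.0, 1.0]), 3, seed=0)

def test_fit_fcm_degenerate_data_warns():
    with pytest.warns(UserWarning, match="degenerate"):
        part = cl.fit_fcm(np.full(5, 0.3), 2, seed=0)
    assert part.centers.shape[0] == 1

def test_fit_fcm_objective_descent():
    for seed in range(5):
        rng = np.random.default_rng(seed)
        data = np.concatenate([rng.normal(0.2, 0.05, 40), rng.normal(0.8, 0.05, 40)])
        part = cl.fit_fcm(data, 2, seed=seed)
        assert np.all(np.diff(part.objective_trace) <= 1e-9)

def test_fit_fcm_iteration_contract(two_blob_data):
    part = cl.fit_fcm(two_blob_data, 2, seed=1, max_iter=3)
    assert part.iterations_run <= 3


# ---------------------------------------------------------------- pcm


def test_pcm_scales_constant_distances():
    lam = cl.pcm_scales(np.array([[0.3, 0.7], [0.6, 0.4]]), np.full((2, 2), 2.5), 2.0)
    np.testing.assert_allclose(lam, [2.5, 2.5])

def test_pcm_scales_derived():
    lam = cl.pcm_scales(np.array([[1.0], [0.5]]), np.array([[1.0], [4.0]]), 2.0)
    np.testing.assert_allclose(lam, [1.6])

def test_pcm_scales_linear_in_W():
    u = np.array([[0.9], [0.4]])
    d2 = np.array([[0.5], [2.0]])
    np.testing.assert_allclose(
        cl.pcm_scales(u, d2, 2.0, W=2.0), 2 * cl.pcm_scales(u, d2, 2.0, W=1.0)
    )

def test_pcm_typicality_half_and_one():
    assert cl.pcm_typicality(np.array([[3.0]]), [3.0], 2.0)[0, 0] == 0.5
    assert cl.pcm_typicality(np.array([[0.0]]), [3.0], 2.0)[0, 0] == 1.0

def test_pcm_typicality_derived():
    np.testing.assert_allclose(cl.pcm_typicality(np.array([[4.0]]), [1.0], 2.0), [[0.2]])

def test_pcm_typicality_matches_grid_oracle():
    rng = np.random.default_rng(1)
    for _ in range(30):
        d2 = rng.uniform(0.01, 5.0)
        lam = rng.uniform(0.05, 3.0)
        p = rng.uniform(1.5, 3.0)
        t = cl.pcm_typicality(np.array([[d2]]), [lam], p)[0, 0]
        assert abs(t - grid_min_typicality(d2, lam, p)) < 1e-3

def test_pcm_typicality_rejects_bad_params():
    with pytest.raises(ValueError):
        cl.pcm_typicality(np.ones((1, 1)), [1.0], 1.0)
    with pytest.raises(ValueError):
        cl.pcm_typicality(np.ones((1, 1)), [0.0], 2.0)


# ---------------------------------------------------------------- fit_pfcm


def test_fit_pfcm_centers_near_fcm(two_blob_data):
    fcm = cl.fit_fcm(two_blob_data, 2, seed=4)
    part, state = cl.fit_pfcm(two_blob_data, 2, seed=4)
    np.testing.assert_allclose(
        np.sort(part.centers[:, 0]), np.sort(fcm.centers[:, 0]), atol=1e-2
    )
    assert np.all(state.scales > 0)

def test_fit_pfcm_outlier_low_typicality():
    rng = np.random.default_rng(2)
    data = np.concatenate([rng.normal(0.2, 0.03, 50), rng.normal(0.8, 0.03, 50), [10.0]])
    part, state = cl.fit_pfcm(data, 2, seed=2)
    d2 = cl.squared_distances(data.reshape(-1, 1), part.centers)
    t_out = cl.pcm_typicality(d2[-1:], state.scales, 2.0)
    assert np.all(t_out < 0.1)

def test_fit_pfcm_deterministic(two_blob_data):
    a, sa = cl.fit_pfcm(two_blob_data, 2, seed=5)
    b, sb = cl.fit_pfcm(two_blob_data, 2, seed=5)
    np.testing.assert_array_equal(a.memberships, b.memberships)
    np.testing.assert_array_equal(sa.scales, sb.scales)


# ---------------------------------------------------------------- sugeno


def test_sugeno_lambda_zero_is_standard_complement():
    u = np.linspace(0, 1, 11)
    nu, pi = cl.sugeno_hesitation(u, 0.0)
    np.testing.assert_array_equal(nu, 1.0 - u)
    np.testing.assert_array_equal(pi, np.zeros_like(u))

def test_sugeno_boundaries():
    nu, pi = cl.sugeno_hesitation(np.array([0.0, 1.0]), 2.0)
    np.testing.assert_array_equal(nu, [1.0, 0.0])
    np.testing.assert_array_equal(pi, [0.0, 0.0])

def test_sugeno_derived_value():
    nu, pi = cl.sugeno_hesitation(0.5, 2.0)
    assert nu == 0.25 and pi == 0.25

def test_sugeno_rejects_bad_membership():
    with pytest.raises(ValueError):
        cl.sugeno_hesitation(1.5, 2.0)

@settings(max_examples=200, deadline=None)
@given(st.floats(0.0, 1.0), st.floats(0.0, 10.0))
def test_sugeno_identity_property(u, lam):
    nu, pi = cl.sugeno_hesitation(u, lam)
    # pi is the exact remainder by construction; re-summation may round 1 ulp
    assert pi == 1.0 - u - nu
    assert abs(u + nu + pi - 1.0) <= np.finfo(float).eps
    assert pi >= 0.0
    assert cl.star_membership(u, pi) >= u

def test_star_membership_examples():
    assert cl.star_membership(0.0, 0.0) == 0.0
    assert cl.star_membership(1.0, 0.0) == 1.0
    _, pi = cl.sugeno_hesitation(0.5, 2.0)
    assert cl.star_membership(0.5, pi) == 0.75


# ---------------------------------------------------------------- ifcm / ipfcm


def test_fit_ifcm_reduces_to_fcm(two_blob_data):
    a = cl.fit_fcm(two_blob_data, 2, seed=7)
    b = cl.fit_ifcm(two_blob_data, 2, sugeno_lambda=0.0, seed=7)
    np.testing.assert_array_equal(a.memberships, b.memberships)
    np.testing.assert_array_equal(a.centers, b.centers)
    np.testing.assert_array_equal(a.objective_trace, b.objective_trace)

def test_fit_ifcm_centers_near_fcm(two_blob_data):
    a = cl.fit_fcm(two_blob_data, 2, seed=3)
    b = cl.fit_ifcm(two_blob_data, 2, sugeno_lambda=2.0, seed=3)
    np.testing.assert_allclose(
        np.sort(b.centers[:, 0]), np.sort(a.centers[:, 0]), atol=2e-2
    )

def test_fit_ifcm_rows_can_exceed_one(two_blob_data):
    part = cl.fit_ifcm(two_blob_data, 2, sugeno_lambda=2.0, seed=3)
    assert np.any(part.memberships.sum(axis=1) > 1.0)

def test_ipfcm_objective_values():
    assert cl.ipfcm_objective(np.ones((1, 1)), np.zeros((1, 1)), [1.0], 2.0) == 0.0
    val = cl.ipfcm_objective(np.array([[0.5]]), np.array([[1.0]]), [1.0], 2.0)
    assert val == 0.5

def test_fit_ipfcm_reduces_to_pfcm(two_blob_data):
    pa, sa = cl.fit_pfcm(two_blob_data, 2, seed=6)
    pb, sb, ib = cl.fit_ipfcm(two_blob_data, 2, sugeno_lambda=0.0, seed=6)
    np.testing.assert_array_equal(pa.memberships, pb.memberships)
    np.testing.assert_array_equal(pa.centers, pb.centers)
    np.testing.assert_array_equal(sa.scales, sb.scales)
    np.testing.assert_array_equal(pa.objective_trace, pb.objective_trace)

def test_fit_ipfcm_objective_descent():
    for seed in range(5):
        rng = np.random.default_rng(100 + seed)
        data = np.concatenate([rng.normal(0.2, 0.05, 60), rng.normal(0.8, 0.05, 60)])
        part, _, _ = cl.fit_ipfcm(data, 2, sugeno_lambda=2.0, seed=seed)
        assert np.all(np.diff(part.objective_trace) <= 1e-9)

def test_fit_ipfcm_outlier_recovery():
    rng = np.random.default_rng(42)
    clean = np.concatenate([rng.normal(0.2, 0.03, 90), rng.normal(0.8, 0.03, 90)])
    noisy = clean.copy()
    idx = rng.choice(clean.size, 18, replace=False)
    noisy[idx] = rng.uniform(1.2, 2.0, 18)
    ref = np.sort(cl.fit_fcm(clean, 2, seed=0).centers[:, 0])
    part, _, _ = cl.fit_ipfcm(noisy, 2, sugeno_lambda=2.0, seed=0)
    assert np.max(np.abs(np.sort(part.centers[:, 0]) - ref)) < 0.05

def test_fit_ipfcm_contract(two_blob_data):
    part, state, ipar = cl.fit_ipfcm(two_blob_data, 2, seed=8, max_iter=50)
    assert part.iterations_run <= 50
    assert part.converged
    assert state.typicalities.shape == (6, 2)
    assert np.all(ipar.star_memberships >= 0)


# ---------------------------------------------------------------- otsu


def test_otsu_between_modes():
    vals = np.array([1, 1, 2, 8, 9, 9], dtype=float)
    thr = cl.otsu_threshold(vals)
    assert 2 < thr < 8
    np.testing.assert_allclose(thr, otsu_exhaustive(vals))

def test_otsu_two_values_lowest_cut():
    img = np.array([0.0] * 10 + [255.0] * 10)
    thr = cl.otsu_threshold(img)
    assert thr == otsu_exhaustive(img)
    assert thr < 2.0  # lowest maximizing cut

def test_otsu_constant_image_errors():
    with pytest.raises(ValueError, match="degenerate"):
        cl.otsu_threshold(np.full((4, 4), 7.0))

def test_otsu_matches_exhaustive_oracle():
    rng = np.random.default_rng(5)
    for _ in range(10):
        vals = np.concatenate(
            [rng.normal(0.3, 0.05, 100), rng.normal(0.7, 0.08, 150)]
        )
        np.testing.assert_allclose(cl.otsu_threshold(vals), otsu_exhaustive(vals))


# ---------------------------------------------------------------- labels / accuracy


def test_labels_from_partition():
    part = cl.FuzzyPartition(
        np.array([[0.8, 0.2], [0.5, 0.5], [0.1, 0.9]]), np.zeros((2, 1)), 2.0, 1, True
    )
    np.testing.assert_array_equal(cl.labels_from_partition(part), [0, 0, 1])

def test_accuracy_identity_and_swap():
    truth = np.array([[0, 1], [1, 0]])
    assert cl.segmentation_accuracy(truth, truth) == 1.0
    assert cl.segmentation_accuracy(1 - truth, truth) == 1.0

def test_accuracy_matches_brute_force():
    rng = np.random.default_rng(11)
    for _ in range(20):
        a = rng.integers(0, 3, 60)
        b = rng.integers(0, 3, 60)
        assert cl.segmentation_accuracy(a, b) == pytest.approx(accuracy_brute(a, b))

def test_accuracy_permutation_invariance():
    rng = np.random.default_rng(13)
    labels = rng.integers(0, 4, (10, 10))
    truth = rng.integers(0, 4, (10, 10))
    base = cl.segmentation_accuracy(labels, truth)
    for perm in itertools.permutations(range(4)):
        relabeled = np.asarray(perm)[labels]
        assert cl.segmentation_accuracy(relabeled, truth) == pytest.approx(base)

def test_accuracy_shape_mismatch():
    with pytest.raises(ValueError):
        cl.segmentation_accuracy(np.zeros((2, 2)), np.zeros((3, 3)))

def test_accuracy_label_cap():
    with pytest.raises(ValueError, match="8 labels"):
        cl.segmentation_accuracy(np.arange(9), np.arange(9))
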