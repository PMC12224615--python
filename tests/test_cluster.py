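"""Soft assignment, target sharpening, objective, gradients and the fit loop."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from gdesce import (
    Centroids,
    RunConfig,
    compute_tolerance,
    fit,
    init_centroids_louvain,
    loss,
    loss_gradients,
    soft_assign,
    target_distribution,
)


def _naive_soft_assign(f, c, alpha):
    n, K = len(f), len(c)
    s = np.zeros((n, K))
    for i in range(n):
        for j in range(K):
            s[i, j] = 1.0 / (1.0 + np.sum((f[i] - c[j]) ** 2) / alpha)
        s[i] /= s[i].sum()
    return s


class TestSoftAssign:
    def test_equidistant_point_is_split_evenly(self):
        f = np.array([[0.0, 0.0]])
        c = np.array([[1.0, 0.0], [-1.0, 0.0]])
        np.testing.assert_allclose(soft_assign(f, c), [[0.5, 0.5]])

    def test_point_at_centroid_with_unit_distance_alternative(self):
        # unnormalized kernel values (1, 1/2) -> row (2/3, 1/3)
        f = np.array([[0.0]])
        c = np.array([[0.0], [1.0]])
        np.testing.assert_allclose(soft_assign(f, c, alpha=1.0), [[2 / 3, 1 / 3]])

    @given(arrays(float, (5, 3), elements=st.floats(-5, 5)),
           arrays(float, (2, 3), elements=st.floats(-5, 5)))
    @settings(max_examples=30, deadline=None)
    def test_rows_sum_to_one(self, f, c):
        s = soft_assign(f, c)
        np.testing.assert_allclose(s.sum(axis=1), 1.0, atol=1e-9)
        assert (s > 0).all() and (s <= 1).all()

    def test_matches_naive_double_loop(self):
        rng = np.random.default_rng(0)
        f, c = rng.normal(size=(10, 4)), rng.normal(size=(3, 4))
        np.testing.assert_allclose(
            soft_assign(f, c, 1.3), _naive_soft_assign(f, c, 1.3), atol=1e-10
        )


class TestTargetDistribution:
    def test_one_hot_is_fixed_point(self):
        s = np.eye(3)[[0, 1, 2, 0]]
        np.testing.assert_allclose(target_distribution(s), s, atol=1e-12)

    def test_uniform_is_fixed_point(self):
        s = np.full((6, 4), 0.25)
        np.testing.assert_allclose(target_distribution(s), s, atol=1e-12)

    def test_single_cell_frequency_term_collapses(self):
        s = np.array([[0.8, 0.2]])
        np.testing.assert_allclose(target_distribution(s), [[0.8, 0.2]], atol=1e-12)

    def test_matches_naive_double_loop(self):
        rng = np.random.default_rng(1)
        s = rng.dirichlet(np.ones(3), size=10)
        n, K = s.shape
        t = np.zeros_like(s)
        for i in range(n):
            for j in range(K):
                t[i, j] = s[i, j] ** 2 / s[:, j].sum()
            t[i] /= t[i].sum()
        np.testing.assert_allclose(target_distribution(s), t, atol=1e-10)


class TestLoss:
    def test_zero_when_t_equals_s_squared(self):
        rng = np.random.default_rng(0)
        s = rng.dirichlet(np.ones(3), size=5)
        assert loss(s, s ** 2) == pytest.approx(0.0, abs=1e-12)

    def test_one_hot_matching_argmax_closed_form(self):
        s = np.array([[0.9, 0.1], [0.7, 0.3]])
        t = np.array([[1.0, 0.0], [1.0, 0.0]])
        expected = np.log(1 / 0.9 ** 2) + np.log(1 / 0.7 ** 2)
        assert loss(s, t) == pytest.approx(expected, abs=1e-12)

    def test_matches_naive_double_loop(self):
        rng = np.random.default_rng(2)
        s = rng.dirichlet(np.ones(3), size=10)
        t = target_distribution(s)
        naive = sum(
            t[i, j] ** 2 * np.log(t[i, j] / max(s[i, j], 1e-12) ** 2)
            for i in range(10) for j in range(3) if t[i, j] > 0
        )
        assert loss(s, t) == pytest.approx(naive, abs=1e-10)


class TestGradients:
    def test_symmetric_point_has_no_gradient_along_axis(self):
        f = np.array([[0.0, 0.5]])
        c = np.array([[1.0, 0.0], [-1.0, 0.0]])
        t = np.array([[0.5, 0.5]])
        gf, _ = loss_gradients(f, c, t)
        assert gf[0, 0] == pytest.approx(0.0, abs=1e-12)

    def test_translation_invariance(self):
        rng = np.random.default_rng(3)
        f, c = rng.normal(size=(6, 3)), rng.normal(size=(2, 3))
        t = target_distribution(soft_assign(f, c))
        gf, gc = loss_gradients(f, c, t)
        np.testing.assert_allclose(gf.sum(0) + gc.sum(0), 0, atol=1e-10)

    @pytest.mark.parametrize("trial", range(5))
    def test_matches_central_finite_differences(self, trial):
        rng = np.random.default_rng(100 + trial)
        n, K, d = 5, 2, 3
        f, c = rng.normal(size=(n, d)), rng.normal(size=(K, d))
        alpha = float(rng.uniform(0.5, 2.0))
        t = target_distribution(soft_assign(f, c, alpha))
        gf, gc = loss_gradients(f, c, t, alpha)
        eps = 1e-6

        def L(fv, cv):
            return loss(soft_assign(fv, cv, alpha), t)

        num_gf = np.zeros_like(f)
        for i in range(n):
            for k in range(d):
                fp, fm = f.copy(), f.copy()
                fp[i, k] += eps
                fm[i, k] -= eps
                num_gf[i, k] = (L(fp, c) - L(fm, c)) / (2 * eps)
        num_gc = np.zeros_like(c)
        for j in range(K):
            for k in range(d):
                cp, cm = c.copy(), c.copy()
                cp[j, k] += eps
                cm[j, k] -= eps
                num_gc[j, k] = (L(f, cp) - L(f, cm)) / (2 * eps)
        scale = max(np.abs(num_gf).max(), np.abs(num_gc).max(), 1e-8)
        assert np.abs(gf - num_gf).max() / scale < 1e-5
        assert np.abs(gc - num_gc).max() / scale < 1e-5


class TestTolerance:
    def test_identical_is_zero(self):
        assert compute_tolerance([1, 2, 3], [1, 2, 3]) == 0.0

    def test_one_change_in_hundred(self):
        a = np.zeros(100, int)
        b = a.copy()
        b[17] = 1
        assert compute_tolerance(b, a) == 0.01

    def test_all_changed_is_one(self):
        assert compute_tolerance([1, 1], [0, 0]) == 1.0

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError, match="length"):
            compute_tolerance([1, 2], [1])


def _two_blobs(n_per=100, sep=10.0, sigma=0.1, d=2, seed=0):
    rng = np.random.default_rng(seed)
    means = np.zeros((2, d))
    means[1, 0] = sep
    labels = np.repeat([0, 1], n_per)
    return means[labels] + sigma * rng.normal(size=(2 * n_per, d)), labels, means


class TestLouvainInit:
    def test_two_blobs_give_two_accurate_centroids(self):
        # resolution chosen for blob size: modularity at resolution 1.0
        # subdivides dense 100-point blobs, a known Louvain behavior
        f, labels, means = _two_blobs()
        centroids, member = init_centroids_louvain(f, knn_k=15, resolution=0.1, seed=0)
        assert centroids.K == 2
        # match communities to blobs by proximity
        for mean in means:
            err = np.abs(centroids.values - mean).min(axis=0).max()
            assert err < 3 * 0.1 / np.sqrt(100)

    def test_duplicating_points_preserves_k(self):
        f, _, _ = _two_blobs()
        _, member = init_centroids_louvain(f, knn_k=15, resolution=0.1, seed=0)
        dup, _ = init_centroids_louvain(np.vstack([f, f]), knn_k=15,
                                        resolution=0.1, seed=0)
        assert dup.K == len(np.unique(member))

    def test_fixed_seed_reproduces_partition(self):
        f, _, _ = _two_blobs(seed=3)
        _, m1 = init_centroids_louvain(f, knn_k=10, seed=42)
        _, m2 = init_centroids_louvain(f, knn_k=10, seed=42)
        np.testing.assert_array_equal(m1, m2)

    def test_too_few_points_raises(self):
        with pytest.raises(ValueError, match="more cells"):
            init_centroids_louvain(np.zeros((5, 2)), knn_k=10)


class TestFit:
    def test_fixed_point_start_stops_at_first_tolerance_check(self):
        f, labels, means = _two_blobs()
        cfg = RunConfig(seed=0, tol_threshold=0.005, learning_rate=0.001)
        res = fit(f, cfg, init=(Centroids(means), labels))
        assert res.n_epochs == 1
        assert res.tol_trace[-1] < cfg.tol_threshold

    def test_tol_threshold_one_stops_after_one_epoch(self):
        rng = np.random.default_rng(0)
        f = rng.normal(size=(50, 2))
        cfg = RunConfig(seed=0, tol_threshold=1.0, knn_k=5)
        res = fit(f, cfg)
        assert res.n_epochs == 1

    def test_row_stochasticity_and_label_range(self):
        f, labels, means = _two_blobs(seed=5)
        cfg = RunConfig(seed=0, max_epochs=5, tol_threshold=1e-9)
        res = fit(f, cfg, init=(Centroids(means), labels))
        np.testing.assert_allclose(res.soft.sum(axis=1), 1.0, atol=1e-9)
        assert set(np.unique(res.labels)) <= set(range(res.K))

    def test_centroid_permutation_permutes_labels(self):
        f, labels, means = _two_blobs(seed=6)
        cfg = RunConfig(seed=0, max_epochs=3, tol_threshold=1e-9)
        res1 = fit(f, cfg, init=(Centroids(means), labels))
        res2 = fit(f, cfg, init=(Centroids(means[::-1]), 1 - labels))
        np.testing.assert_array_equal(res1.labels, 1 - res2.labels)

    def test_full_batch_small_lr_loss_nonincreasing_on_fixed_target(self):
        rng = np.random.default_rng(7)
        f = rng.normal(size=(30, 2))
        c = rng.normal(size=(3, 2))
        s = soft_assign(f, c)
        t = target_distribution(s)
        prev = loss(s, t)
        lr = 1e-3
        for _ in range(20):
            gf, gc = loss_gradients(f, c, t)
            f = f - lr * gf
            c = c - lr * gc
            cur = loss(soft_assign(f, c), t)
            assert cur <= prev + 1e-9
            prev = cur

    def test_epoch_cap_respected(self):
        rng = np.random.default_rng(8)
        f = rng.normal(size=(60, 2))
        cfg = RunConfig(seed=0, max_epochs=4, tol_threshold=1e-12, knn_k=5)
        res = fit(f, cfg)
        assert res.n_epochs <= 4
        assert len(res.tol_trace) == res.n_epochs
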