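"""Normalization, HVG selection and grid-density outlier filtering."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gdesce import (
    CountMatrix,
    Embedding2D,
    build_grid,
    euclidean_distance,
    generate_points2d,
    normalize_counts,
    remove_outliers,
    select_hvg,
)


def _counts(values, batch=None):
    values = np.asarray(values)
    n, g = values.shape
    return CountMatrix(
        values,
        cell_ids=[f"c{i}" for i in range(n)],
        gene_ids=[f"g{j}" for j in range(g)],
        batch=batch,
    )


class TestNormalize:
    def test_library_scaling_to_10k_before_log(self):
        # one cell with counts [1,1,2]: scaled values 2500/2500/5000
        m = _counts([[1, 1, 2], [4, 3, 1]])
        norm = normalize_counts(m)
        np.testing.assert_allclose(
            np.expm1(norm.log_values[0]), [2500.0, 2500.0, 5000.0]
        )

    def test_zero_total_cell_error_names_cell(self):
        m = _counts([[1, 2], [0, 0]])
        with pytest.raises(ValueError, match="c1"):
            normalize_counts(m)

    def test_constant_gene_column_becomes_zeros_with_warning(self):
        # identical cells: every log-normalized column is constant
        m = _counts([[2, 2], [2, 2], [2, 2]])
        with pytest.warns(UserWarning, match="zero-variance"):
            norm = normalize_counts(m)
        np.testing.assert_array_equal(norm.values, np.zeros((3, 2)))

    def test_columns_standardized(self):
        rng = np.random.default_rng(0)
        m = _counts(rng.integers(1, 50, size=(40, 6)))
        norm = normalize_counts(m)
        np.testing.assert_allclose(norm.values.mean(axis=0), 0, atol=1e-6)
        np.testing.assert_allclose(norm.values.std(axis=0), 1, atol=1e-6)

    def test_by_batch_standardizes_within_each_batch(self):
        rng = np.random.default_rng(1)
        batch = np.array(["a"] * 20 + ["b"] * 30)
        m = _counts(rng.integers(1, 50, size=(50, 5)), batch=batch)
        norm = normalize_counts(m, by_batch=True)
        for b in ("a", "b"):
            sub = norm.values[batch == b]
            np.testing.assert_allclose(sub.mean(axis=0), 0, atol=1e-6)
            np.testing.assert_allclose(sub.std(axis=0), 1, atol=1e-6)

    def test_unstandardize_recovers_log_values(self):
        rng = np.random.default_rng(2)
        batch = np.array(["a"] * 15 + ["b"] * 15)
        m = _counts(rng.integers(1, 30, size=(30, 8)), batch=batch)
        for by_batch in (False, True):
            norm = normalize_counts(m, by_batch=by_batch)
            np.testing.assert_allclose(
                norm.unstandardize(), norm.log_values, atol=1e-10
            )


class TestSelectHVG:
    def test_identical_genes_tie_break_by_order(self):
        x = np.tile(np.linspace(0, 1, 10)[:, None], (1, 6))
        mask = select_hvg(x, 3)
        np.testing.assert_array_equal(mask, [True, True, True, False, False, False])

    def test_planted_high_dispersion_gene_selected(self):
        rng = np.random.default_rng(0)
        x = 1.0 + 0.01 * rng.normal(size=(100, 20))
        x[:, 7] = np.where(rng.random(100) < 0.5, 0.1, 3.0)  # bimodal, high var
        mask = select_hvg(x, 1)
        assert mask[7] and mask.sum() == 1

    def test_all_genes_is_identity_mask(self):
        rng = np.random.default_rng(1)
        x = rng.random((20, 5))
        assert select_hvg(x, 5).all()

    def test_too_many_requested_raises(self):
        with pytest.raises(ValueError, match="exceeds"):
            select_hvg(np.ones((4, 3)), 4)

    def test_agrees_with_naive_reimplementation(self):
        # independent double-loop: same binned-dispersion definition
        rng = np.random.default_rng(3)
        x = rng.gamma(2.0, 1.0, size=(60, 30))
        mean = x.mean(0)
        disp = x.var(0) / mean
        order = np.argsort(mean, kind="stable")
        nbins = max(1, min(20, 30 // 5))  # same >=5-genes-per-bin rule
        norm_disp = np.empty(30)
        bins = {}
        for rank, gidx in enumerate(order):
            bins.setdefault(min(rank * nbins // 30, nbins - 1), []).append(gidx)
        for members in bins.values():
            d = disp[members]
            sd = d.std()
            for gi in members:
                norm_disp[gi] = 0.0 if sd == 0 else (disp[gi] - d.mean()) / sd
        expected = np.zeros(30, bool)
        expected[np.argsort(-norm_disp, kind="stable")[:10]] = True
        np.testing.assert_array_equal(select_hvg(x, 10), expected)


class TestEuclidean:
    def test_3_4_5_triangle(self):
        assert euclidean_distance((0, 0), (3, 4)) == 5.0

    def test_identity(self):
        assert euclidean_distance((2.5, -1), (2.5, -1)) == 0.0

    @given(st.tuples(*[st.floats(-1e3, 1e3) for _ in range(4)]))
    @settings(max_examples=50, deadline=None)
    def test_symmetry(self, coords):
        a, b = coords[:2], coords[2:]
        assert euclidean_distance(a, b) == euclidean_distance(b, a)


class TestBuildGrid:
    def test_colocated_points_single_dense_cell(self):
        e = generate_points2d([((1.0, 1.0), 10, 0.0)])
        grid = build_grid(e, 4, 5)
        assert grid.counts.sum() == 10
        assert (grid.counts > 0).sum() == 1
        assert grid.dense_mask[grid.counts.argmax()]

    def test_zero_threshold_makes_every_nonempty_cell_dense(self):
        rng = np.random.default_rng(0)
        e = Embedding2D(rng.random((30, 2)))
        grid = build_grid(e, 5, 0)
        np.testing.assert_array_equal(grid.dense_mask, grid.counts > 0)

    def test_unit_square_corners_one_per_cell(self):
        e = Embedding2D(np.array([[0, 0], [0, 1], [1, 0], [1, 1]], float))
        grid = build_grid(e, 2, 0)
        np.testing.assert_array_equal(np.sort(grid.counts), [1, 1, 1, 1])

    def test_counts_sum_to_points(self):
        rng = np.random.default_rng(1)
        e = Embedding2D(rng.normal(size=(200, 2)))
        grid = build_grid(e, 7, 3)
        assert grid.counts.sum() == 200


def straggler_fixture():
    """20 co-located points plus one far straggler (known outlier)."""
    return generate_points2d(
        [((0.0, 0.0), 20, 0.0)], stragglers=[(10.0, 10.0)], seed=7
    )


class TestRemoveOutliers:
    def test_straggler_removed_cluster_kept(self):
        e = straggler_fixture()
        keep = remove_outliers(e, 5, 3)
        assert keep[:20].all() and not keep[20]

    def test_idempotent_on_survivors(self):
        e = straggler_fixture()
        keep = remove_outliers(e, 5, 3)
        again = remove_outliers(Embedding2D(e.coords[keep]), 5, 3)
        assert again.all()

    def test_single_blob_all_kept(self):
        e = generate_points2d([((0.0, 0.0), 200, 1.0)], seed=1)
        assert remove_outliers(e, 5, 3).all()

    def test_permutation_invariance(self):
        e = straggler_fixture()
        rng = np.random.default_rng(0)
        perm = rng.permutation(e.n)
        keep = remove_outliers(e, 5, 3)
        keep_perm = remove_outliers(Embedding2D(e.coords[perm]), 5, 3)
        np.testing.assert_array_equal(keep_perm, keep[perm])

    def test_all_isolated_falls_back_to_keeping_everything(self):
        # a diagonal of single points: no cell ever dense
        pts = np.column_stack([np.arange(6, dtype=float)] * 2)
        with pytest.warns(UserWarning, match="keeping"):
            keep = remove_outliers(Embedding2D(pts), 6, 3)
        assert keep.all()
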