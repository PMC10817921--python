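import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cellsift import (
    CellMapping,
    DistanceSpec,
    binned_mapping,
    distance_kernel,
    knn_kernel,
    mapping_kernel,
    precomputed_kernel,
)

ROW_TOL = 1e-8


def mapping_kernel_oracle(T, src, tgt):
    """Triple-loop evaluation of the double-normalized mapping kernel:
    K_ij = sum_mu p(mu | cell_i) * p(cell_j | mu)."""
    T = np.asarray(T, dtype=float)
    K = np.zeros((len(src), len(tgt)))
    col_mass = T[tgt].sum(axis=0)
    for a, i in enumerate(src):
        row_mass = T[i].sum()
        for b, j in enumerate(tgt):
            for mu in range(T.shape[1]):
                if col_mass[mu] == 0:
                    continue
                K[a, b] += (T[i, mu] / row_mass) * (T[j, mu] / col_mass[mu])
    return K


class TestMappingKernel:
    def test_one_hot_gives_within_class_averaging(self, onehot_ab):
        K = mapping_kernel(onehot_ab)
        expected = [[0.5, 0.5, 0.0], [0.5, 0.5, 0.0], [0.0, 0.0, 1.0]]
        np.testing.assert_allclose(K.toarray(), expected)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_triple_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        T = CellMapping(rng.random((50, 5)))
        K = mapping_kernel(T)
        oracle = mapping_kernel_oracle(T.T, np.arange(50), np.arange(50))
        assert np.abs(K.toarray() - oracle).max() <= 1e-10

    def test_oracle_agreement_with_masks(self, rng):
        T = CellMapping(rng.random((40, 4)))
        src, tgt = np.arange(25), np.arange(20, 40)
        K = mapping_kernel(T, src, tgt)
        oracle = mapping_kernel_oracle(T.T, src, tgt)
        assert np.abs(K.toarray() - oracle).max() <= 1e-10
        assert np.abs(K.row_sums() - 1).max() <= ROW_TOL

    def test_zero_target_mass_column_dropped_with_warning(self):
        # label 'b' exists only outside the target set
        T = CellMapping.from_labels(["a", "a", "b", "a"])
        with pytest.warns(UserWarning, match="zero mass"):
            K = mapping_kernel(T, source_index=[0, 1, 3], target_index=[0, 1, 3])
        assert np.abs(K.row_sums() - 1).max() <= ROW_TOL

    def test_source_cell_mapping_nowhere_errors(self):
        T = CellMapping.from_labels(["a", "a", "b"])
        with pytest.warns(UserWarning):
            with pytest.raises(ValueError, match="zero mapping mass"):
                mapping_kernel(T, source_index=[2], target_index=[0, 1])

    def test_negative_mapping_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            mapping_kernel(CellMapping(np.array([[1.0], [-1.0]])))


class TestBinnedMapping:
    def test_half_open_bins_with_max_closed(self):
        # [0, 0.5) / [0.5, 1.0]: the midpoint falls in the upper bin, the
        # maximum is closed into the last bin
        m = binned_mapping([0.0, 0.5, 1.0], M=2)
        np.testing.assert_array_equal(m.T, [[1, 0], [0, 1], [0, 1]])
        assert m.bins == 2 and m.kind == "labels"

    def test_twelve_bin_pseudotime(self, rng):
        psd = rng.uniform(0, 1, size=100)
        m = binned_mapping(psd, M=12)
        assert m.T.shape == (100, 12)
        np.testing.assert_allclose(m.T.sum(axis=1), 1.0)

    def test_matches_floor_oracle(self, rng):
        v = rng.uniform(0, 1, size=1000)
        M = 4
        m = binned_mapping(v, M)
        width = (v.max() - v.min()) / M
        oracle = np.minimum(((v - v.min()) // width).astype(int), M - 1)
        np.testing.assert_array_equal(m.T.argmax(axis=1), oracle)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            binned_mapping([2.0, 2.0, 2.0], M=3)

    def test_single_bin_rejected(self):
        with pytest.raises(ValueError, match="M must be >= 2"):
            binned_mapping([0.0, 1.0], M=1)


class TestKnnKernel:
    def test_nearest_neighbor_on_line(self, line_mapping):
        K = knn_kernel(line_mapping, DistanceSpec(k=1), weighting="binary")
        expected = [[0, 1, 0], [1, 0, 0], [0, 1, 0]]
        np.testing.assert_allclose(K.toarray(), expected)

    def test_complete_graph_uniform(self, rng):
        T = CellMapping(rng.normal(size=(12, 3)))
        K = knn_kernel(T, DistanceSpec(k=11), weighting="binary")
        np.testing.assert_allclose(K.toarray(), np.where(~np.eye(12, dtype=bool), 1 / 11, 0.0))

    def test_k_too_large_rejected(self, line_mapping):
        with pytest.raises(ValueError, match="smaller than the target"):
            knn_kernel(line_mapping, DistanceSpec(k=3))

    def test_ties_keep_lowest_target_index(self):
        # cells 1 and 2 equidistant from cell 0
        T = CellMapping(np.array([[0.0], [1.0], [-1.0], [5.0]]))
        K = knn_kernel(T, DistanceSpec(k=1), weighting="binary")
        assert K.toarray()[0, 1] == 1.0 and K.toarray()[0, 2] == 0.0

    @pytest.mark.parametrize("weighting", ["umap", "binary", "inverse_distance"])
    def test_support_subset_of_exhaustive_knn(self, rng, weighting):
        pts = rng.normal(size=(100, 5)) + rng.integers(0, 5, size=(100, 1)) * 3.0
        T = CellMapping(pts)
        k = 15
        K = knn_kernel(T, DistanceSpec(k=k), weighting=weighting)
        assert np.abs(K.row_sums() - 1).max() <= ROW_TOL
        D = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
        np.fill_diagonal(D, np.inf)
        dense = K.toarray()
        for i in range(100):
            kth = np.sort(D[i])[k - 1]
            allowed = set(np.flatnonzero(D[i] <= kth + 1e-12))
            support = set(np.flatnonzero(dense[i] > 0))
            assert support <= allowed
            assert len(support) == k

    def test_rectangular_case_control_kernel(self, rng):
        T = CellMapping(rng.normal(size=(30, 4)))
        src, tgt = np.arange(20, 30), np.arange(20)
        K = knn_kernel(T, DistanceSpec(k=5), src, tgt)
        assert K.shape == (10, 20)
        assert np.abs(K.row_sums() - 1).max() <= ROW_TOL

    def test_include_self_flag(self, line_mapping):
        K = knn_kernel(line_mapping, DistanceSpec(k=1), weighting="binary",
                       include_self=True)
        np.testing.assert_allclose(K.toarray(), np.eye(3))


class TestDistanceKernel:
    def test_gamma_zero_is_uniform(self, rng):
        T = CellMapping(rng.normal(size=(9, 2)))
        K = distance_kernel(T, DistanceSpec(gamma=0.0))
        np.testing.assert_allclose(K.toarray(), 1 / 9)

    def test_worked_row_on_line(self, line_mapping):
        K = distance_kernel(line_mapping, DistanceSpec(gamma=1.0))
        np.testing.assert_allclose(
            K.toarray()[0], [0.70539, 0.25950, 0.03511], atol=1e-5
        )

    def test_rows_are_distributions(self, rng):
        T = CellMapping(rng.normal(size=(60, 7)))
        K = distance_kernel(T, DistanceSpec(gamma=2.5))
        arr = K.toarray()
        assert np.all(arr >= 0)
        assert np.abs(arr.sum(axis=1) - 1).max() <= ROW_TOL

    def test_manhattan_equals_euclidean_in_1d(self, rng):
        T = CellMapping(rng.normal(size=(25, 1)))
        Ke = distance_kernel(T, DistanceSpec(metric="euclidean", gamma=1.3))
        Km = distance_kernel(T, DistanceSpec(metric="manhattan", gamma=1.3))
        np.testing.assert_allclose(Ke.toarray(), Km.toarray(), atol=1e-12)

    def test_auto_gamma_recorded(self, rng):
        T = CellMapping(rng.normal(size=(20, 2)))
        K = distance_kernel(T)
        assert K.params["gamma"] > 0

    def test_stability_at_large_gamma(self, rng):
        T = CellMapping(100.0 * rng.normal(size=(15, 2)))
        K = distance_kernel(T, DistanceSpec(gamma=50.0))
        assert np.isfinite(K.toarray()).all()
        assert np.abs(K.row_sums() - 1).max() <= ROW_TOL


class TestPrecomputedKernel:
    def test_identity_accepted(self):
        K = precomputed_kernel(np.eye(3))
        np.testing.assert_array_equal(K.toarray(), np.eye(3))

    def test_renormalize_divides_rows(self):
        K = precomputed_kernel(np.array([[2.0, 2.0], [1.0, 3.0]]), renormalize=True)
        np.testing.assert_allclose(K.toarray(), [[0.5, 0.5], [0.25, 0.75]])

    def test_non_stochastic_rejected_without_renormalize(self):
        with pytest.raises(ValueError, match="row-stochastic"):
            precomputed_kernel(np.array([[0.6, 0.3]]))

    def test_negative_and_zero_row_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            precomputed_kernel(np.array([[1.5, -0.5]]))
        with pytest.raises(ValueError, match="zero rows"):
            precomputed_kernel(np.array([[0.0, 0.0], [0.5, 0.5]]))


@settings(deadline=None, max_examples=25, derandomize=True)
@given(
    seed=st.integers(0, 2**16),
    n=st.integers(5, 40),
    m=st.integers(1, 6),
    kind=st.sampled_from(["mapping", "distance", "knn"]),
)
def test_row_stochasticity_property(seed, n, m, kind):
    """Every kernel family yields rows summing to one on random inputs."""
    rng = np.random.default_rng(seed)
    if kind == "mapping":
        T = CellMapping(rng.random((n, m)) + 0.01)
        K = mapping_kernel(T)
    elif kind == "distance":
        T = CellMapping(rng.normal(size=(n, m)))
        K = distance_kernel(T, DistanceSpec(gamma=float(rng.uniform(0.1, 5))))
    else:
        T = CellMapping(rng.normal(size=(n, m)))
        K = knn_kernel(T, DistanceSpec(k=min(5, n - 1)), weighting="binary")
    assert K.max_row_sum_deviation() <= ROW_TOL


def test_kernels_ignore_feature_order_of_expression(rng):
    """Kernels depend only on the mapping T, not on X's gene order."""
    T = CellMapping(rng.normal(size=(10, 2)))
    K1 = distance_kernel(T, DistanceSpec(gamma=1.0))
    K2 = distance_kernel(T, DistanceSpec(gamma=1.0))
    np.testing.assert_array_equal(K1.toarray(), K2.toarray())
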