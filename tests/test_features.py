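"""PSC, connectivity graphs, kernel bases and graph reduction."""

import numpy as np
import pytest

from conftest import brute_force_pearson
from pilvq.features import (
    ROITimeSeries,
    assemble_feature_table,
    build_functional_basis,
    build_spatial_basis,
    compute_graph_matrix,
    compute_psc,
    default_n_kernels,
    reduce_graph,
)


def make_ts(Y, n_s=None, coords=None):
    Y = np.asarray(Y, dtype=float)
    T = Y.shape[1]
    n_s = T // 2 if n_s is None else n_s
    return ROITimeSeries(
        Y=Y,
        coords=coords if coords is not None else np.zeros((Y.shape[0], 3)),
        structured_idx=np.arange(n_s),
        random_idx=np.arange(n_s, T),
    )


class TestPSC:
    def test_hand_example_single_voxel(self):
        # structured mean 5, random mean 3 -> (5-3)/(5+3) = 0.25
        ts = make_ts([[4, 6, 2, 4]], n_s=2)
        assert compute_psc(ts) == pytest.approx(0.25)

    def test_opposite_voxels_cancel(self):
        # per-voxel PSC +0.25 and -0.25 average to zero
        ts = make_ts([[4, 6, 2, 4], [2, 4, 4, 6]], n_s=2)
        assert compute_psc(ts) == pytest.approx(0.0, abs=1e-15)

    def test_equal_condition_means_give_zero(self):
        ts = make_ts([[3, 5, 5, 3], [1, 2, 2, 1]], n_s=2)
        assert compute_psc(ts) == pytest.approx(0.0, abs=1e-15)

    def test_scale_invariance(self, rng):
        Y = 100 + rng.normal(0, 1, (5, 12))
        ts = make_ts(Y)
        ts2 = make_ts(3.7 * Y)
        assert compute_psc(ts2) == pytest.approx(compute_psc(ts), rel=1e-12)

    def test_zero_denominator_names_voxel(self):
        ts = make_ts([[1, -3, 2, 0], [1, 2, 3, 4]], n_s=2)
        with pytest.raises(ZeroDivisionError, match="0"):
            compute_psc(ts)

    def test_textual_denominator_variant_doubles(self):
        ts = make_ts([[4, 6, 2, 4]], n_s=2)
        assert compute_psc(ts, denominator="mean") == pytest.approx(0.5)


class TestGraphMatrix:
    def test_matches_brute_force_pearson(self, rng):
        Y = rng.normal(size=(10, 20))
        G = compute_graph_matrix(make_ts(Y)).G
        assert np.allclose(G, brute_force_pearson(Y), atol=1e-12)

    def test_diagonal_is_one(self, rng):
        G = compute_graph_matrix(make_ts(rng.normal(size=(6, 15)))).G
        assert np.array_equal(np.diag(G), np.ones(6))

    def test_perfect_anticorrelation(self):
        y = np.array([1.0, 2.0, 4.0, 3.0])
        G = compute_graph_matrix(make_ts(np.vstack([y, -y]))).G
        assert G[0, 1] == pytest.approx(-1.0)

    def test_hand_value(self):
        # series (1,2,3) vs (1,3,2): covariance 1/3, each sd sqrt(2/3) -> 0.5
        G = compute_graph_matrix(np.array([[1.0, 2, 3], [1, 3, 2]])).G
        assert G[0, 1] == pytest.approx(0.5)

    def test_zero_variance_voxel_named(self):
        with pytest.raises(ValueError, match="voxel"):
            compute_graph_matrix(make_ts([[1, 1, 1, 1], [1, 2, 3, 4]]))


class TestSpatialBasis:
    def test_default_kernel_counts_for_study_rois(self):
        assert default_n_kernels(32) == 3
        assert default_n_kernels(82) == 4
        assert default_n_kernels(126) == 8

    def test_two_blobs_recovered_exactly(self, rng):
        c1 = rng.normal(0, 0.5, (20, 3))
        c2 = rng.normal(0, 0.5, (20, 3)) + [20, 0, 0]
        coords = np.vstack([c1, c2])
        basis = build_spatial_basis(coords, n_kernels=2, seed=0)
        labels = basis.labels
        # oracle: nearest-blob-centre assignment
        truth = (np.linalg.norm(coords - [20, 0, 0], axis=1)
                 < np.linalg.norm(coords, axis=1)).astype(int)
        same = (labels == truth).all() or (labels == 1 - truth).all()
        assert same

    def test_single_kernel_reduces_to_1x1(self, rng):
        coords = rng.normal(size=(10, 3))
        basis = build_spatial_basis(coords, n_kernels=1, seed=0)
        G = compute_graph_matrix(make_ts(rng.normal(size=(10, 20)))).G
        assert reduce_graph(G, basis).X_tilde.shape == (1, 1)

    def test_k_must_be_below_v(self, rng):
        with pytest.raises(ValueError):
            build_spatial_basis(rng.normal(size=(5, 3)), n_kernels=5)


class TestFunctionalBasis:
    def _block_graph(self, V, rng, flip=False):
        labels = np.repeat([0, 1], V // 2)
        if flip:
            labels = labels[::-1]
        G = np.where(labels[:, None] == labels[None, :], 0.9, 0.05)
        np.fill_diagonal(G, 1.0)
        return G + rng.normal(0, 0.01, (V, V)) * 0, labels

    def test_unanimous_subjects_reproduce_their_clustering(self, rng):
        V = 12
        G, labels = self._block_graph(V, rng)
        coords = rng.normal(size=(V, 3))
        basis = build_functional_basis([G, G, G], coords, n_kernels=2)
        got = basis.labels
        same = (got == labels).all() or (got == 1 - labels).all()
        assert same

    def test_planted_blocks_recovered(self, rng):
        V = 16
        labels = np.repeat([0, 1], V // 2)
        graphs = []
        for _ in range(5):
            noise = rng.normal(0, 0.05, (V, V))
            noise = 0.5 * (noise + noise.T)
            G = np.where(labels[:, None] == labels[None, :], 0.8, 0.1) + noise
            np.fill_diagonal(G, 1.0)
            graphs.append(np.clip(G, -1, 1))
        basis = build_functional_basis(graphs, rng.normal(size=(V, 3)), 2)
        got = basis.labels
        assert (got == labels).all() or (got == 1 - labels).all()

    def test_single_subject_rejected(self, rng):
        G, _ = self._block_graph(8, rng)
        with pytest.raises(ValueError, match="2 subjects"):
            build_functional_basis([G], rng.normal(size=(8, 3)), 2)


class TestReduceGraph:
    def test_identity_basis_is_identity_map(self, rng):
        from pilvq.features import SmoothingBasis

        G = compute_graph_matrix(make_ts(rng.normal(size=(4, 30)))).G
        basis = SmoothingBasis(P=np.eye(4), kernels=[], grouping_mode="spatial")
        assert np.allclose(reduce_graph(G, basis).X_tilde, G)

    def test_hand_reduction(self):
        from pilvq.features import SmoothingBasis

        G = np.array([[1.0, 0.5], [0.5, 1.0]])
        basis = SmoothingBasis(P=np.array([[1.0], [1.0]]), kernels=[],
                               grouping_mode="spatial")
        assert reduce_graph(G, basis).X_tilde == pytest.approx(np.array([[3.0]]))

    def test_symmetry_and_rank(self, rng):
        from pilvq.features import SmoothingBasis

        V, K = 10, 3
        G = compute_graph_matrix(make_ts(rng.normal(size=(V, 25)))).G
        P = np.abs(rng.normal(size=(V, K)))
        basis = SmoothingBasis(P=P, kernels=[], grouping_mode="spatial")
        X = reduce_graph(G, basis).X_tilde
        assert np.array_equal(X, X.T)
        assert np.linalg.matrix_rank(X) <= K

    def test_voxel_permutation_invariance(self, rng):
        from pilvq.features import SmoothingBasis

        V, K = 8, 2
        G = compute_graph_matrix(make_ts(rng.normal(size=(V, 25)))).G
        P = np.abs(rng.normal(size=(V, K)))
        perm = rng.permutation(V)
        X1 = reduce_graph(G, SmoothingBasis(P=P, kernels=[], grouping_mode="spatial"))
        X2 = reduce_graph(
            G[np.ix_(perm, perm)],
            SmoothingBasis(P=P[perm], kernels=[], grouping_mode="spatial"),
        )
        assert np.allclose(X1.X_tilde, X2.X_tilde, atol=1e-12)

    def test_dimension_mismatch(self, rng):
        from pilvq.features import SmoothingBasis

        G = np.eye(5)
        basis = SmoothingBasis(P=np.ones((4, 2)), kernels=[], grouping_mode="spatial")
        with pytest.raises(ValueError):
            reduce_graph(G, basis)


class TestFeatureTable:
    def _values(self, subjects):
        vals = {}
        for s in subjects:
            for roi in ("cerebellar", "frontal", "subcortical"):
                for ses in ("pre", "post"):
                    vals[(s, roi, ses)] = hash((s, roi, ses)) % 100 / 100
        return vals

    def test_full_table_shape_and_columns(self):
        subjects = [f"s{i}" for i in range(34)]
        table = assemble_feature_table(self._values(subjects), "PSC")
        assert table.shape == (34, 6)
        assert list(table.columns) == [
            "PSC-Cerebellar-Pre", "PSC-Cerebellar-Post",
            "PSC-Frontal-Pre", "PSC-Frontal-Post",
            "PSC-Subcortical-Pre", "PSC-Subcortical-Post",
        ]

    def test_empty_input_keeps_schema(self):
        table = assemble_feature_table({}, "SGF")
        assert table.shape == (0, 6)

    def test_missing_cell_identifies_subject(self):
        vals = self._values(["a"])
        del vals[("a", "frontal", "post")]
        with pytest.raises(ValueError, match="a.*Frontal.*Post"):
            assemble_feature_table(vals, "PSC")

    def test_duplicate_cell_rejected(self):
        vals = {("a", "frontal", "post"): 1.0, ("a", "Frontal", "Post"): 2.0}
        with pytest.raises(ValueError, match="duplicate"):
            assemble_feature_table(vals, "PSC")
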