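"""Patch feature extraction, exact KNN search, and graph construction."""

import numpy as np
import pytest
import scipy.sparse as sp

from npgtv import (
    NoiseModel,
    PatchConfig,
    auto_kernel_bandwidth,
    build_weighted_graph,
    extract_patch_features,
    grid_graph,
    knn_edges,
    make_phantom,
)
from npgtv.patch_graph import (
    PatchFeatureSet,
    WeightedGraph,
    load_edge_list,
    save_edge_list,
)


def features_from_matrix(X):
    return PatchFeatureSet(features=np.asarray(X, dtype=float), image_shape=(X.shape[0], 1))


class TestExtractPatchFeatures:
    def test_row_count_and_length(self, rng):
        img = rng.random((5, 5))
        feats = extract_patch_features(img, PatchConfig(patch_size=3, lambda_spatial=0.1))
        assert feats.features.shape == (25, 11)

    def test_lambda_zero_drops_coordinates(self, rng):
        img = rng.random((8, 8))
        feats = extract_patch_features(img, PatchConfig(patch_size=3, lambda_spatial=0.0))
        assert np.all(feats.features[:, -2:] == 0.0)

    def test_constant_image_gives_identical_rows(self):
        img = np.full((8, 8), 0.4)
        feats = extract_patch_features(img, PatchConfig(patch_size=3, lambda_spatial=0.0))
        assert np.all(feats.features == feats.features[0])

    def test_center_pixel_is_patch_middle(self, rng):
        img = rng.random((7, 9))
        s = 3
        feats = extract_patch_features(img, PatchConfig(patch_size=s, lambda_spatial=0.0))
        centers = feats.features[:, s * s // 2].reshape(7, 9)
        assert np.allclose(centers, img)

    def test_normalized_coord_mode(self, rng):
        img = rng.random((9, 9))
        feats = extract_patch_features(
            img, PatchConfig(patch_size=3, lambda_spatial=1.0, coord_mode="normalized")
        )
        assert feats.features[:, -2:].max() == pytest.approx(1.0)

    def test_patch_too_large_rejected(self, rng):
        img = rng.random((8, 8))
        with pytest.raises(ValueError):
            extract_patch_features(img, PatchConfig(patch_size=9))

    def test_even_patch_size_rejected(self):
        with pytest.raises(ValueError):
            PatchConfig(patch_size=4)


class TestKnnEdges:
    def test_hand_computed_line_example(self):
        # 1-D features at positions 0, 1, 3 with K=1: 0->1, 1->0, 2->1
        feats = features_from_matrix(np.array([[0.0], [1.0], [3.0]]))
        idx, dist = knn_edges(feats, K=1, backend="brute")
        assert idx.ravel().tolist() == [1, 0, 1]
        assert dist.ravel().tolist() == [1.0, 1.0, 2.0]

    def test_every_node_has_k_out_edges_no_self(self, rng):
        feats = features_from_matrix(rng.random((30, 4)))
        idx, _ = knn_edges(feats, K=4)
        assert idx.shape == (30, 4)
        assert all(i not in idx[i] for i in range(30))

    def test_matches_full_pairwise_sort_oracle(self, rng):
        X = rng.random((30, 3))
        feats = features_from_matrix(X)
        idx, dist = knn_edges(feats, K=4, backend="brute")
        d2 = ((X[:, None, :] - X[None, :, :]) ** 2).sum(-1)
        for i in range(30):
            order = [j for j in np.argsort(d2[i], kind="stable") if j != i][:4]
            assert idx[i].tolist() == order
            assert np.allclose(dist[i], np.sqrt(d2[i, order]))

    def test_backends_agree(self, rng):
        feats = features_from_matrix(rng.random((50, 5)))
        idx_b, dist_b = knn_edges(feats, K=3, backend="brute")
        idx_t, dist_t = knn_edges(feats, K=3, backend="kdtree")
        assert np.array_equal(idx_b, idx_t)
        assert np.allclose(dist_b, dist_t)

    def test_tie_break_by_ascending_index(self):
        # four coincident points: the K nearest of node 3 are 0, 1 in index order
        feats = features_from_matrix(np.zeros((4, 2)))
        idx, _ = knn_edges(feats, K=2, backend="brute")
        assert idx[3].tolist() == [0, 1]

    def test_k_too_large_rejected(self, rng):
        feats = features_from_matrix(rng.random((5, 2)))
        with pytest.raises(ValueError):
            knn_edges(feats, K=5)


class TestBuildWeightedGraph:
    def test_kernel_values(self):
        # d=0 -> w=1; d=sigma -> w=e^-1
        idx = np.array([[1], [0]])
        dist = np.array([[0.0], [0.0]])
        g = build_weighted_graph(idx, dist, sigma_kernel=0.5)
        assert g.weight(0, 1) == 1.0
        dist = np.array([[0.5], [0.5]])
        g = build_weighted_graph(idx, dist, sigma_kernel=0.5)
        assert g.weight(0, 1) == pytest.approx(np.exp(-1.0), rel=1e-12)

    def test_union_symmetrization_exact(self, rng):
        X = rng.random((40, 6))
        feats = features_from_matrix(X)
        idx, dist = knn_edges(feats, K=3)
        g = build_weighted_graph(idx, dist, sigma_kernel=1.0)
        assert (g.W != g.W.T).nnz == 0
        assert np.all(g.W.diagonal() == 0)
        assert np.all(g.degrees() >= 3)  # union keeps out-degree >= K
        assert g.W.data.min() > 0 and g.W.data.max() <= 1.0

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(ValueError):
            build_weighted_graph(np.array([[1], [0]]), np.zeros((2, 1)), sigma_kernel=0.0)


class TestAutoKernelBandwidth:
    def test_stated_formula(self):
        # s=5, sigma=25.5 (0.1 on the unit scale): sigma_k^2 = 0.2*25*0.01
        got = auto_kernel_bandwidth(NoiseModel(sigma=25.5, seed=0), PatchConfig(patch_size=5))
        assert got == pytest.approx(np.sqrt(0.05), rel=1e-12)

    def test_zero_noise_fallback(self):
        got = auto_kernel_bandwidth(NoiseModel(sigma=0, seed=0), PatchConfig(patch_size=5))
        assert got == 0.1

    def test_bandwidth_scales_linearly_with_patch_size(self):
        nm = NoiseModel(sigma=20, seed=0)
        s5 = auto_kernel_bandwidth(nm, PatchConfig(patch_size=5))
        s9 = auto_kernel_bandwidth(nm, PatchConfig(patch_size=9))
        assert s9 / s5 == pytest.approx(9 / 5, rel=1e-12)


class TestGridGraph:
    @pytest.mark.parametrize("m,l,conn,edges", [(2, 2, 4, 4), (3, 3, 4, 12), (3, 3, 8, 20)])
    def test_lattice_edge_counts(self, m, l, conn, edges):
        g = grid_graph(m, l, conn)
        assert g.num_edges == edges

    def test_symmetric_zero_diagonal(self):
        g = grid_graph(4, 5, 8)
        assert (g.W != g.W.T).nnz == 0
        assert np.all(g.W.diagonal() == 0)

    def test_too_small_rejected(self):
        with pytest.raises(ValueError):
            grid_graph(1, 5, 4)


class TestGraphInvariants:
    def test_permutation_consistency(self, rng):
        X = rng.random((20, 3))
        perm = rng.permutation(20)
        idx, dist = knn_edges(features_from_matrix(X), K=3, backend="brute")
        g = build_weighted_graph(idx, dist, 1.0)
        idx_p, dist_p = knn_edges(features_from_matrix(X[perm]), K=3, backend="brute")
        g_p = build_weighted_graph(idx_p, dist_p, 1.0)
        P = sp.csr_matrix((np.ones(20), (np.arange(20), perm)), shape=(20, 20))
        assert abs(P @ g.W @ P.T - g_p.W).max() < 1e-14

    def test_large_lambda_recovers_spatial_neighbors(self, rng):
        # with a huge spatial weight the K nearest features are the K nearest pixels
        img = rng.random((16, 16))
        feats = extract_patch_features(img, PatchConfig(patch_size=3, lambda_spatial=1e3))
        idx, _ = knn_edges(feats, K=4, backend="brute")
        rows, cols = np.mgrid[0:16, 0:16]
        coords = np.column_stack([rows.ravel(), cols.ravel()]).astype(float)
        for i in range(16 * 16):
            r, c = divmod(i, 16)
            if not (1 <= r <= 14 and 1 <= c <= 14):
                continue  # interior pixels have an unambiguous 4-neighborhood
            d2 = ((coords - coords[i]) ** 2).sum(1)
            spatial = {j for j in np.argsort(d2, kind="stable") if j != i}
            expected = set(list(sorted(spatial, key=lambda j: (d2[j], j)))[:4])
            assert set(idx[i].tolist()) == expected

    def test_edge_list_round_trip(self, rng, tmp_path):
        X = rng.random((15, 4))
        idx, dist = knn_edges(features_from_matrix(X), K=3)
        g = build_weighted_graph(idx, dist, 0.7)
        path = tmp_path / "graph.txt"
        save_edge_list(g, path)
        g2 = load_edge_list(path)
        assert abs(g.W - g2.W).max() < 1e-15


class TestWeightedGraphValidation:
    def test_asymmetric_rejected(self):
        W = sp.csr_matrix(np.array([[0.0, 1.0], [0.5, 0.0]]))
        with pytest.raises(ValueError):
            WeightedGraph(W)

    def test_nonzero_diagonal_rejected(self):
        W = sp.csr_matrix(np.array([[1.0, 1.0], [1.0, 0.0]]))
        with pytest.raises(ValueError):
            WeightedGraph(W)
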