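"""Connectivity vectors, distances, Gcst selection, tvDFC and hubs."""

import numpy as np
import pytest

from tvdfc.netmetrics import (
    band_average_distances,
    band_selection_test,
    connectivity_vector,
    eigenvector_centrality,
    global_threshold,
    group_pair_distances,
    hub_adjacency,
    hub_significance,
    paired_band_comparison,
    temporal_variability,
)


class TestConnectivityVector:
    def test_empty_mask_zeroes_everything(self):
        v = connectivity_vector(np.zeros(6, bool), np.full(6, 0.7))
        assert not v.weights.any()

    def test_full_mask_passes_mean_plv_through(self):
        w = np.linspace(0.1, 0.9, 6)
        v = connectivity_vector(np.ones(6, bool), w)
        np.testing.assert_array_equal(v.weights, w)

    def test_length_is_preserved_and_mismatch_rejected(self):
        v = connectivity_vector(np.zeros(10, bool), np.zeros(10))
        assert v.weights.shape == (10,)
        with pytest.raises(ValueError, match="differ"):
            connectivity_vector(np.zeros(3, bool), np.zeros(4))


class TestDistances:
    def test_identical_vectors_have_zero_distance(self):
        d = group_pair_distances({1: np.ones(5), 2: np.ones(5)})
        assert d[(1, 2)] == 0.0

    def test_three_four_five(self):
        d = group_pair_distances({1: np.zeros(3), 2: np.array([3, 4, 0.0])})
        assert d[(1, 2)] == 5.0

    def test_eight_groups_give_28_pairs(self):
        rng = np.random.default_rng(0)
        d = group_pair_distances({g: rng.random(10) for g in range(1, 9)})
        assert len(d) == 28

    def test_distance_axioms(self):
        rng = np.random.default_rng(1)
        u, v = rng.random(8), rng.random(8)
        d = group_pair_distances({1: u, 2: v, 3: u.copy()})
        assert d[(1, 2)] >= 0
        assert d[(1, 3)] == 0.0  # identity of indiscernibles, exact zero
        d2 = group_pair_distances({1: v, 2: u})
        assert d[(1, 2)] == d2[(1, 2)]  # symmetry

    def test_band_average_pools_segments(self):
        per_seg = {
            s: {(1, 2): float(s + 1), (1, 3): 2.0, (2, 3): 2.0}
            for s in range(9)
        }
        avg = band_average_distances(per_seg)
        assert avg[(1, 2)] == 5.0  # mean of 1..9
        assert avg[(1, 3)] == 2.0

    def test_missing_segment_is_reported(self):
        per_seg = {s: {(1, 2): 1.0} for s in range(8)}
        with pytest.raises(ValueError, match="missing segments"):
            band_average_distances(per_seg)

    def test_global_threshold_grand_mean(self):
        bands = {
            b: {(1, 2): float(v)}
            for b, v in zip("abcdef", [1, 2, 3, 4, 5, 6])
        }
        assert global_threshold(bands) == 3.5
        ones = {b: {(1, 2): 1.0, (1, 3): 1.0} for b in "abc"}
        assert global_threshold(ones) == 1.0


class TestBandSelection:
    def test_closed_form_example(self):
        r = band_selection_test([9, 10, 11], gcst=8.0, n_bands=1)
        assert r.t == pytest.approx(2 * np.sqrt(3))
        assert r.df == 2
        assert r.cohens_d == pytest.approx(2.0)

    def test_values_at_threshold_give_null_result(self):
        r = band_selection_test([8.0, 8.0, 8.0], gcst=8.0)
        assert r.t == 0.0 and r.cohens_d == 0.0 and not r.selected

    def test_zero_variance_off_threshold_is_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            band_selection_test([9.0, 9.0, 9.0], gcst=8.0)

    def test_bonferroni_scaling_and_clipping(self):
        r1 = band_selection_test([9, 10, 11], gcst=8.0, n_bands=1)
        r6 = band_selection_test([9, 10, 11], gcst=8.0, n_bands=6)
        assert r6.p == pytest.approx(min(1.0, r1.p * 6))

    def test_df_is_27_for_28_group_pairs(self):
        rng = np.random.default_rng(2)
        r = band_selection_test(rng.random(28) + 8, gcst=8.0)
        assert r.df == 27

    def test_paired_comparison_identities(self):
        x = [1.0, 2.0, 3.0]
        r = paired_band_comparison(x, x)
        assert r["t"] == 0.0 and r["p"] == 1.0
        r2 = paired_band_comparison(
            [2.001, 3.002, 4.001], [1.0, 2.0, 3.0]
        )
        assert r2["t"] > 0

    def test_paired_comparison_matches_one_sample_oracle(self):
        from scipy.stats import ttest_1samp

        rng = np.random.default_rng(3)
        a, b = rng.random(28), rng.random(28)
        r = paired_band_comparison(a, b)
        o = ttest_1samp(a - b, 0.0)
        assert r["t"] == pytest.approx(o.statistic)
        assert r["p"] == pytest.approx(o.pvalue)


class TestTemporalVariability:
    def test_constant_sequence_has_zero_variability(self):
        assert temporal_variability(np.tile([1.0, 2.0, 3.0], (9, 1))) == 0.0

    def test_two_segment_case_is_the_distance(self):
        assert temporal_variability(np.array([[0.0, 0.0], [3.0, 4.0]])) == 5.0

    def test_alternating_sequence_gives_the_gap_norm(self):
        u, v = np.array([1.0, 0.0]), np.array([0.0, 2.0])
        seq = np.array([u, v, u, v, u])
        assert temporal_variability(seq) == pytest.approx(np.hypot(1, 2))

    def test_coordinate_permutation_invariance(self):
        rng = np.random.default_rng(4)
        x = rng.random((9, 12))
        perm = rng.permutation(12)
        assert temporal_variability(x) == pytest.approx(
            temporal_variability(x[:, perm])
        )

    def test_single_segment_is_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            temporal_variability(np.ones((1, 5)))


class TestEigenvectorCentrality:
    def test_star_center_dominates(self):
        adj = np.zeros((5, 5))
        adj[0, 1:] = adj[1:, 0] = 1.0
        c = eigenvector_centrality(adj)
        assert c[0] > c[1:].max()
        assert np.linalg.norm(c) == pytest.approx(1.0)

    def test_complete_graph_is_uniform(self):
        n = 7
        adj = np.ones((n, n)) - np.eye(n)
        np.testing.assert_allclose(
            eigenvector_centrality(adj), 1 / np.sqrt(n), atol=1e-10
        )

    def test_matches_dense_eigendecomposition_on_random_graphs(self):
        rng = np.random.default_rng(5)
        checked = 0
        while checked < 8:
            a = (rng.random((20, 20)) < 0.25) * rng.random((20, 20))
            a = np.triu(a, 1)
            a = a + a.T
            from scipy.sparse.csgraph import connected_components
            from scipy.sparse import csr_matrix

            if not a.any():
                continue
            ncc, _ = connected_components(csr_matrix(a), directed=False)
            if ncc != 1:
                continue
            w, v = np.linalg.eigh(a)
            oracle = np.abs(v[:, -1])
            oracle /= np.linalg.norm(oracle)
            np.testing.assert_allclose(
                eigenvector_centrality(a), oracle, atol=1e-8
            )
            checked += 1

    def test_disconnected_graph_scores_largest_component(self):
        adj = np.zeros((6, 6))
        adj[0, 1] = adj[1, 0] = 1.0  # 2-node component
        for i, j in [(2, 3), (3, 4), (4, 5), (2, 4)]:  # 4-node component
            adj[i, j] = adj[j, i] = 1.0
        c = eigenvector_centrality(adj)
        assert c[0] == c[1] == 0.0
        assert (c[2:] > 0).all()

    def test_bipartite_graph_converges(self):
        # even cycle: bipartite spectrum, handled by the spectral shift
        n = 6
        adj = np.zeros((n, n))
        for i in range(n):
            adj[i, (i + 1) % n] = adj[(i + 1) % n, i] = 1.0
        np.testing.assert_allclose(
            eigenvector_centrality(adj), 1 / np.sqrt(n), atol=1e-9
        )

    def test_empty_graph_is_rejected(self):
        with pytest.raises(ValueError, match="no edges"):
            eigenvector_centrality(np.zeros((4, 4)))


class TestHubs:
    def test_embedded_star_center_is_flagged(self):
        rng = np.random.default_rng(6)
        n = 14
        adj = np.zeros((n, n))
        iu = np.triu_indices(n, 1)
        noise = rng.random(iu[0].size) < 0.08
        adj[iu[0][noise], iu[1][noise]] = 0.4
        adj[0, 1:8] = 1.0  # strong star on node 0
        adj = np.maximum(adj, adj.T)
        hubs = hub_significance(adj, n_random=400, seed=1)
        assert hubs[0].is_hub

    def test_same_seed_reproduces_hub_set(self):
        rng = np.random.default_rng(7)
        n = 10
        a = (rng.random((n, n)) < 0.3).astype(float)
        a = np.triu(a, 1)
        a = a + a.T
        h1 = hub_significance(a, n_random=200, seed=5)
        h2 = hub_significance(a, n_random=200, seed=5)
        assert [h.is_hub for h in h1] == [h.is_hub for h in h2]

    def test_pure_random_graphs_are_calibrated(self):
        # hub fraction on Erdos-Renyi inputs stays near alpha
        rng = np.random.default_rng(8)
        n, runs = 12, 40
        frac = []
        for r in range(runs):
            a = np.zeros((n, n))
            iu = np.triu_indices(n, 1)
            m = rng.random(iu[0].size) < 0.3
            a[iu[0][m], iu[1][m]] = 1.0
            a = a + a.T
            if not a.any():
                continue
            hubs = hub_significance(a, n_random=300, alpha=0.05, seed=r)
            frac.append(np.mean([h.is_hub for h in hubs]))
        assert np.mean(frac) <= 0.05 + 0.02

    def test_degenerate_density_is_rejected(self):
        n = 5
        full = np.ones((n, n)) - np.eye(n)
        with pytest.raises(ValueError, match="degenerate"):
            hub_significance(full, n_random=10, seed=0)

    def test_hub_adjacency_pools_union_of_masks(self):
        pairs = [(0, 1), (0, 2), (1, 2)]
        masks = [np.array([True, False, False]),
                 np.array([True, True, False])]
        weights = [np.array([0.8, 0.5, 0.9]), np.array([0.6, 0.4, 0.9])]
        adj = hub_adjacency(masks, weights, pairs, 3)
        assert adj[0, 1] == pytest.approx(0.7)  # mean of 0.8, 0.6
        assert adj[0, 2] == pytest.approx(0.4)  # significant once
        assert adj[1, 2] == 0.0  # never significant
        assert np.allclose(adj, adj.T)
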