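"""Weighted graph-topology metrics against analytic values and brute force."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import fcgraph as fg
from fcgraph.graph import ThresholdedGraph, _round_half_away

from _oracles import (char_path_length_brute, floyd_warshall,
                      global_efficiency_brute, harmonic_closeness_brute,
                      onnela_clustering_brute, random_weighted_graph,
                      strength_brute)


def complete_graph(n: int, w: float = 1.0) -> ThresholdedGraph:
    m = np.full((n, n), w)
    np.fill_diagonal(m, 0.0)
    return ThresholdedGraph(m, density=1.0)


def path3(w01: float = 1.0, w12: float = 1.0) -> ThresholdedGraph:
    m = np.zeros((3, 3))
    m[0, 1] = m[1, 0] = w01
    m[1, 2] = m[2, 1] = w12
    return ThresholdedGraph(m, density=2 / 3)


class TestCanonicalGraphs:
    def test_complete_unit_graph(self):
        g = complete_graph(8)
        assert np.allclose(fg.nodal_clustering(g), 1.0)
        assert np.allclose(fg.nodal_closeness(g), 1.0)
        assert fg.global_efficiency(g) == pytest.approx(1.0)
        assert fg.characteristic_path_length(g)[0] == pytest.approx(1.0)
        assert np.allclose(fg.nodal_strength(g), 7.0)

    def test_three_node_unit_path(self):
        g = path3()
        assert fg.global_efficiency(g) == pytest.approx(5 / 6)
        L, frac = fg.characteristic_path_length(g)
        assert L == pytest.approx(4 / 3)
        assert frac == 0.0
        close = fg.nodal_closeness(g)
        assert close[1] == pytest.approx(1.0)
        assert close[0] == close[2] == pytest.approx(3 / 4)

    def test_three_node_weighted_path_strengths(self):
        g = path3(0.2, 0.5)
        assert np.allclose(fg.nodal_strength(g), [0.2, 0.7, 0.5])

    def test_star_graph_no_triangles(self):
        m = np.zeros((6, 6))
        m[0, 1:] = m[1:, 0] = 0.7
        g = ThresholdedGraph(m, density=1 / 3)
        assert np.allclose(fg.nodal_clustering(g), 0.0)

    def test_triangle_with_weak_edge(self):
        # weights (1, 1, 0.125): C = 0.125^(1/3) = 0.5 at every node
        m = np.zeros((3, 3))
        m[0, 1] = m[1, 0] = 1.0
        m[0, 2] = m[2, 0] = 1.0
        m[1, 2] = m[2, 1] = 0.125
        g = ThresholdedGraph(m, density=1.0)
        assert np.allclose(fg.nodal_clustering(g), 0.5)

    def test_isolated_node(self):
        m = np.zeros((4, 4))
        m[0, 1] = m[1, 0] = 1.0
        m[1, 2] = m[2, 1] = 1.0
        g = ThresholdedGraph(m, density=0.5)
        assert fg.nodal_strength(g)[3] == 0.0
        assert fg.nodal_closeness(g)[3] == 0.0

    def test_disconnected_dyads(self):
        m = np.zeros((4, 4))
        m[0, 1] = m[1, 0] = 1.0
        m[2, 3] = m[3, 2] = 1.0
        g = ThresholdedGraph(m, density=1 / 3)
        L, frac = fg.characteristic_path_length(g)
        assert L == pytest.approx(1.0)
        assert frac == pytest.approx(2 / 3)


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(8))
    def test_metrics_match_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 30))
        w = random_weighted_graph(rng, n, density=float(rng.uniform(0.15, 0.6)))
        if not (w > 0).any():
            pytest.skip("empty draw")
        g = ThresholdedGraph(w, density=0.3)
        assert np.allclose(fg.nodal_strength(g), strength_brute(w), atol=1e-10)
        assert np.allclose(fg.nodal_clustering(g), onnela_clustering_brute(w),
                           atol=1e-10)
        d = fg.shortest_path_lengths(g)
        d_ref = floyd_warshall(w)
        finite = np.isfinite(d_ref)
        assert np.array_equal(np.isfinite(d), finite)
        assert np.allclose(d[finite], d_ref[finite], atol=1e-10)
        assert np.allclose(fg.nodal_closeness(g), harmonic_closeness_brute(w),
                           atol=1e-10)
        assert fg.global_efficiency(g) == pytest.approx(
            global_efficiency_brute(w), abs=1e-10)
        if finite[~np.eye(n, dtype=bool)].any():
            assert fg.characteristic_path_length(g)[0] == pytest.approx(
                char_path_length_brute(w), abs=1e-10)

    def test_clustering_matches_networkx(self, rng):
        """Cross-check the Onnela variant against networkx's implementation."""
        import networkx as nx
        w = random_weighted_graph(rng, 20, density=0.4)
        g = ThresholdedGraph(w, density=0.4)
        G = nx.from_numpy_array(w)
        ref = np.array([nx.clustering(G, weight="weight")[i] for i in range(20)])
        assert np.allclose(fg.nodal_clustering(g), ref, atol=1e-10)


class TestDensityThreshold:
    def test_edge_count_at_study_dimensions(self, rng):
        # 141 nodes at 15%: round(0.15 * 9870) = round(1480.5) = 1481
        v = rng.normal(size=(141, 141))
        v = (v + v.T) / 2
        np.fill_diagonal(v, 0.0)
        g = fg.apply_density_threshold(v, 0.15)
        assert g.n_edges == 1481

    def test_round_half_away_from_zero(self):
        assert _round_half_away(1480.5) == 1481
        assert _round_half_away(2.5) == 3
        assert _round_half_away(2.4) == 2

    def test_all_negative_matrix_rejected(self):
        v = -np.ones((6, 6))
        np.fill_diagonal(v, 0.0)
        with pytest.raises(ValueError, match="positive"):
            fg.apply_density_threshold(v, 0.5)

    def test_full_density_keeps_all_positive(self, rng):
        v = np.abs(rng.normal(size=(10, 10))) + 0.1
        v = (v + v.T) / 2
        np.fill_diagonal(v, 0.0)
        g = fg.apply_density_threshold(v, 1.0)
        assert np.allclose(g.weights, v)

    def test_negatives_zeroed_and_top_k_kept(self):
        v = np.array([[0, 0.9, -0.5, 0.1],
                      [0.9, 0, 0.4, -0.2],
                      [-0.5, 0.4, 0, 0.3],
                      [0.1, -0.2, 0.3, 0]])
        g = fg.apply_density_threshold(v, 2 / 6)
        assert g.n_edges == 2
        assert g.weights[0, 1] == 0.9 and g.weights[1, 2] == 0.4
        assert g.weights[2, 3] == 0.0 and g.weights[0, 2] == 0.0

    def test_truncated_when_too_few_positives(self):
        v = np.zeros((6, 6))
        v[0, 1] = v[1, 0] = 0.5
        with pytest.warns(UserWarning, match="positive"):
            g = fg.apply_density_threshold(v, 0.9)
        assert g.truncated and g.n_edges == 1


class TestRewireNull:
    def test_degree_sequence_preserved(self, rng):
        w = random_weighted_graph(rng, 25, density=0.3)
        g = ThresholdedGraph(w, density=0.3)
        null = fg.rewire_null(g, seed=5)
        assert np.array_equal(np.sort(fg.nodal_degree(null)),
                              np.sort(fg.nodal_degree(g)))
        # node-wise, not just sorted
        assert np.array_equal(fg.nodal_degree(null), fg.nodal_degree(g))
        # weight multiset preserved
        iu = np.triu_indices(25, k=1)
        assert np.allclose(np.sort(null.weights[iu][null.weights[iu] > 0]),
                           np.sort(w[iu][w[iu] > 0]))

    def test_complete_graph_returned_unchanged(self):
        g = complete_graph(6, 0.4)
        null = fg.rewire_null(g, seed=1)
        assert np.allclose(null.weights, g.weights)

    def test_ring_lattice_clustering_destroyed(self):
        # 100-node ring lattice, degree 6: rewiring should at least halve C
        n, k = 100, 6
        m = np.zeros((n, n))
        for i in range(n):
            for off in range(1, k // 2 + 1):
                j = (i + off) % n
                m[i, j] = m[j, i] = 1.0
        g = ThresholdedGraph(m, density=k / (n - 1))
        c_lattice = fg.nodal_clustering(g).mean()
        null = fg.rewire_null(g, n_swaps_per_edge=10, seed=3)
        c_null = fg.nodal_clustering(null).mean()
        assert c_null < 0.5 * c_lattice


class TestSmallWorldness:
    def test_complete_graph_sigma_exactly_one(self):
        res = fg.small_worldness(complete_graph(10), n_nulls=3, seed=0)
        assert res.sigma == pytest.approx(1.0)
        assert res.null_clustering_sd == 0.0

    def test_sigma_reproducible(self, rng):
        w = random_weighted_graph(rng, 30, density=0.2)
        g = ThresholdedGraph(w, density=0.2)
        a = fg.small_worldness(g, n_nulls=10, seed=42)
        b = fg.small_worldness(g, n_nulls=10, seed=42)
        assert a.sigma == b.sigma

    def test_n_nulls_validation(self):
        with pytest.raises(ValueError):
            fg.small_worldness(complete_graph(5), n_nulls=1)


class TestIntegration:
    def test_constant_curve_integrates_to_itself(self):
        d = np.linspace(0.15, 0.35, 21)
        assert fg.integrate_over_densities(np.full(21, 3.7), d) == pytest.approx(3.7)

    def test_linear_curve_integrates_to_midpoint(self):
        d = np.linspace(0.15, 0.35, 21)
        curve = np.linspace(2.0, 6.0, 21)
        assert fg.integrate_over_densities(curve, d) == pytest.approx(4.0)

    def test_default_grid_has_21_densities(self):
        assert len(fg.DEFAULT_DENSITIES) == 21
        assert fg.DEFAULT_DENSITIES[0] == 0.15
        assert fg.DEFAULT_DENSITIES[-1] == 0.35

    def test_too_few_densities_rejected(self):
        with pytest.raises(ValueError):
            fg.integrate_over_densities(np.array([1.0]), np.array([0.2]))

    def test_nodal_curves_integrate_per_node(self):
        d = np.array([0.1, 0.2, 0.3])
        curves = np.column_stack([np.full(3, 1.0), np.array([0.0, 1.0, 2.0])])
        out = fg.integrate_over_densities(curves, d)
        assert np.allclose(out, [1.0, 1.0])


class TestProperties:
    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000), scale=st.floats(0.1, 10.0))
    def test_weight_scaling(self, seed, scale):
        """Scaling weights by c scales strength by c, distances by 1/c, and
        leaves degree, max-normalized clustering and closeness ranks alone."""
        rng = np.random.default_rng(seed)
        w = random_weighted_graph(rng, 12, density=0.5)
        if not (w > 0).any():
            return
        g = ThresholdedGraph(w, density=0.5)
        gs = ThresholdedGraph(w * scale, density=0.5)
        assert np.allclose(fg.nodal_strength(gs), scale * fg.nodal_strength(g))
        assert np.array_equal(fg.nodal_degree(gs), fg.nodal_degree(g))
        assert np.allclose(fg.nodal_clustering(gs), fg.nodal_clustering(g),
                           atol=1e-12)
        d, ds = fg.shortest_path_lengths(g), fg.shortest_path_lengths(gs)
        finite = np.isfinite(d)
        assert np.allclose(ds[finite], d[finite] / scale)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_node_relabeling_equivariance(self, seed):
        rng = np.random.default_rng(seed)
        w = random_weighted_graph(rng, 10, density=0.5)
        if not (w > 0).any():
            return
        perm = rng.permutation(10)
        g = ThresholdedGraph(w, density=0.5)
        gp = ThresholdedGraph(w[np.ix_(perm, perm)], density=0.5)
        for metric in (fg.nodal_strength, fg.nodal_clustering, fg.nodal_closeness):
            assert np.allclose(metric(gp), metric(g)[perm], atol=1e-12)

    def test_efficiency_monotone_in_density(self, rng):
        v = rng.normal(size=(40, 40))
        v = (v + v.T) / 2
        np.fill_diagonal(v, 0.0)
        effs = [fg.global_efficiency(fg.apply_density_threshold(v, d))
                for d in (0.15, 0.2, 0.25, 0.3, 0.35)]
        assert all(b >= a - 1e-12 for a, b in zip(effs, effs[1:]))
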