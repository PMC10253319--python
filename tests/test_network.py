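"""DCCM, correlation-network construction, communities and suboptimal paths."""

from itertools import islice

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from allosom.network import (
    CorrelationMatrix,
    average_dccm,
    build_network,
    compute_dccm,
    detect_communities,
    modularity,
    suboptimal_paths,
)
from allosom.structure import AtomSet
from allosom.synthetic import BlockSpec, block_correlated_ensemble

from conftest import make_ensemble, make_structure


def brute_force_dccm(coords):
    """Frame-by-frame double-loop accumulation of the normalized
    displacement covariance — the independent oracle."""
    n_frames, n_sites, _ = coords.shape
    mean = coords.mean(axis=0)
    inner = np.zeros((n_sites, n_sites))
    for f in range(n_frames):
        d = coords[f] - mean
        for i in range(n_sites):
            for j in range(n_sites):
                inner[i, j] += d[i] @ d[j]
    inner /= n_frames
    out = np.empty_like(inner)
    for i in range(n_sites):
        for j in range(n_sites):
            out[i, j] = inner[i, j] / np.sqrt(inner[i, i] * inner[j, j])
    return out


class TestComputeDccm:
    def test_shared_displacement_gives_all_ones(self):
        structure = make_structure(4)
        common = np.random.default_rng(0).normal(size=(30, 1, 3))
        ensemble = make_ensemble(structure, np.repeat(common, 4, axis=1))
        m = compute_dccm(ensemble, AtomSet(np.arange(4)), fit=False)
        np.testing.assert_allclose(m.values, 1.0, atol=1e-10)

    def test_antiphase_pair_gives_minus_one(self, rng):
        structure = make_structure(4)
        disp = rng.normal(0, 0.3, size=(40, 4, 3))
        x = rng.normal(0, 1.0, size=40)
        disp[:, 0, :] = 0.0
        disp[:, 1, :] = 0.0
        disp[:, 0, 0] = x
        disp[:, 1, 0] = -x
        ensemble = make_ensemble(structure, disp)
        m = compute_dccm(ensemble, AtomSet(np.arange(4)), fit=False)
        assert m.values[0, 1] == pytest.approx(-1.0, abs=1e-10)

    def test_matches_brute_force_accumulation(self, rng):
        structure = make_structure(5)
        disp = rng.normal(0, 0.7, size=(200, 5, 3))
        ensemble = make_ensemble(structure, disp)
        m = compute_dccm(ensemble, AtomSet(np.arange(5)), fit=False)
        oracle = brute_force_dccm(structure.coords + disp)
        np.testing.assert_allclose(m.values, oracle, atol=1e-10)

    def test_frozen_site_is_named(self):
        structure = make_structure(3)
        disp = np.zeros((20, 3, 3))
        disp[:, :2] = np.random.default_rng(1).normal(size=(20, 2, 3))
        ensemble = make_ensemble(structure, disp)
        with pytest.raises(ValueError, match="A:3"):
            compute_dccm(ensemble, AtomSet(np.arange(3)), fit=False)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 2**31 - 1))
    def test_output_is_valid_correlation_matrix(self, seed):
        structure = make_structure(4)
        disp = np.random.default_rng(seed).normal(0, 0.5, size=(12, 4, 3))
        ensemble = make_ensemble(structure, disp)
        v = compute_dccm(ensemble, AtomSet(np.arange(4)), fit=False).values
        assert np.allclose(v, v.T)
        assert np.allclose(np.diag(v), 1.0)
        assert np.all(np.abs(v) <= 1 + 1e-12)

    def test_block_structure_recovered_within_sampling_error(self):
        spec = BlockSpec(blocks=[5, 5], rho=0.8, frames=2000, seed=3)
        ensemble = block_correlated_ensemble(spec)
        m = compute_dccm(ensemble, AtomSet(np.arange(10)), fit=False)
        v = m.values
        iu = np.triu_indices(5, 1)
        within = np.concatenate([v[:5, :5][iu], v[5:, 5:][iu]])
        between = v[:5, 5:].ravel()
        se = (1 - 0.8**2) / np.sqrt(spec.frames)
        assert abs(within.mean() - 0.8) < 3 * se
        assert abs(between.mean()) < 3 / np.sqrt(spec.frames)


class TestAverageDccm:
    def _random_matrix(self, seed, n=4):
        rng = np.random.default_rng(seed)
        a = rng.uniform(-1, 1, size=(n, n))
        v = (a + a.T) / 2
        np.fill_diagonal(v, 1.0)
        v = np.clip(v, -1, 1)
        return CorrelationMatrix(v, [f"A:{i}" for i in range(n)])

    def test_self_average_is_identity_operation(self):
        m = self._random_matrix(0)
        np.testing.assert_allclose(average_dccm([m, m]).values, m.values)

    def test_opposite_offdiagonals_cancel(self):
        m = self._random_matrix(1)
        neg = CorrelationMatrix(
            np.where(np.eye(4, dtype=bool), 1.0, -m.values), m.labels
        )
        avg = average_dccm([m, neg]).values
        assert np.allclose(avg[~np.eye(4, dtype=bool)], 0.0)
        assert np.allclose(np.diag(avg), 1.0)

    def test_three_way_mean_matches_arithmetic(self):
        ms = [self._random_matrix(s) for s in (2, 3, 4)]
        avg = average_dccm(ms).values
        expected = (ms[0].values + ms[1].values + ms[2].values) / 3
        np.fill_diagonal(expected, 1.0)
        np.testing.assert_allclose(avg, expected, atol=1e-12)

    def test_label_mismatch_rejected(self):
        a = self._random_matrix(5)
        b = CorrelationMatrix(a.values, [f"B:{i}" for i in range(4)])
        with pytest.raises(ValueError):
            average_dccm([a, b])


class TestBuildNetwork:
    def test_hand_computed_adjacency_and_weights(self):
        v = np.array(
            [
                [1.0, 0.9, 0.3, -0.6],
                [0.9, 1.0, 0.0, 0.2],
                [0.3, 0.0, 1.0, 0.51],
                [-0.6, 0.2, 0.51, 1.0],
            ]
        )
        labels = ["A:1", "A:2", "A:3", "A:4"]
        g = build_network(CorrelationMatrix(v, labels), cutoff=0.5)
        assert set(g.edges) == {("A:1", "A:2"), ("A:1", "A:4"), ("A:3", "A:4")}
        assert g.edges["A:1", "A:2"]["weight"] == pytest.approx(-np.log(0.9))
        assert g.edges["A:1", "A:4"]["weight"] == pytest.approx(-np.log(0.6))
        assert g.edges["A:1", "A:4"]["correlation"] == pytest.approx(-0.6)

    def test_weight_endpoints(self):
        v = np.array([[1.0, 1.0], [1.0, 1.0]])
        g = build_network(CorrelationMatrix(v, ["A:1", "A:2"]), cutoff=0.5)
        assert g.edges["A:1", "A:2"]["weight"] == pytest.approx(0.0)
        v2 = np.array([[1.0, 0.5001], [0.5001, 1.0]])
        g2 = build_network(CorrelationMatrix(v2, ["A:1", "A:2"]), cutoff=0.5)
        assert g2.edges["A:1", "A:2"]["weight"] == pytest.approx(-np.log(0.5001))

    def test_high_cutoff_gives_valid_empty_network(self):
        v = np.array([[1.0, 0.4], [0.4, 1.0]])
        g = build_network(CorrelationMatrix(v, ["A:1", "A:2"]), cutoff=0.9)
        assert g.number_of_edges() == 0
        assert g.number_of_nodes() == 2


def two_clique_graph():
    """Two 6-cliques joined by a single weak bridge."""
    g = nx.Graph()
    left = [f"L{i}" for i in range(6)]
    right = [f"R{i}" for i in range(6)]
    for group in (left, right):
        for i, u in enumerate(group):
            for v in group[i + 1:]:
                g.add_edge(u, v, abs_corr=1.0, weight=0.1)
    g.add_edge("L0", "R0", abs_corr=0.6, weight=0.5)
    return g, set(left), set(right)


def brute_force_modularity(graph, membership, weight="abs_corr"):
    m = sum(d[weight] for _, _, d in graph.edges(data=True))
    q = 0.0
    for u, v, d in graph.edges(data=True):
        if membership[u] == membership[v]:
            q += d[weight] / m
    for c in set(membership.values()):
        deg = sum(
            d[weight]
            for u, v, d in graph.edges(data=True)
            for node in (u, v)
            if membership[node] == c
        )
        q -= (deg / (2 * m)) ** 2
    return q


class TestCommunities:
    def test_two_cliques_recovered_exactly(self):
        g, left, right = two_clique_graph()
        p = detect_communities(g)
        assert p.n_communities == 2
        groups = p.communities()
        assert {frozenset(c) for c in groups} == {frozenset(left), frozenset(right)}

    def test_edgeless_network_gives_singletons(self):
        g = nx.Graph()
        g.add_nodes_from(["A:1", "A:2", "A:3"])
        p = detect_communities(g)
        assert p.n_communities == 3
        assert p.modularity == 0.0

    def test_partition_ids_contiguous_from_one(self):
        g, _, _ = two_clique_graph()
        p = detect_communities(g)
        assert sorted(set(p.membership.values())) == [1, 2]

    def test_deterministic_and_relabel_invariant(self):
        g, _, _ = two_clique_graph()
        p1 = detect_communities(g, seed=1)
        p2 = detect_communities(g, seed=99)
        assert p1.membership == p2.membership
        relabeled = nx.relabel_nodes(g, {n: f"x_{n}" for n in g.nodes})
        p3 = detect_communities(relabeled)
        original = {frozenset(c) for c in p1.communities()}
        mapped = {frozenset(m.removeprefix("x_") for m in c) for c in p3.communities()}
        assert original == mapped


class TestModularity:
    def test_single_community_is_zero(self):
        g, _, _ = two_clique_graph()
        membership = {n: 1 for n in g.nodes}
        assert modularity(g, membership) == pytest.approx(0.0, abs=1e-12)

    def test_two_disconnected_cliques_score_half(self):
        g = nx.Graph()
        for offset, cid in ((0, "a"), (10, "b")):
            for i in range(4):
                for j in range(i + 1, 4):
                    g.add_edge(offset + i, offset + j, abs_corr=1.0)
        membership = {n: (1 if n < 10 else 2) for n in g.nodes}
        assert modularity(g, membership) == pytest.approx(0.5, abs=1e-12)

    def test_matches_brute_force_on_random_partitions(self, rng):
        for seed in range(10):
            g = nx.gnp_random_graph(8, 0.5, seed=seed)
            g = nx.relabel_nodes(g, {n: f"A:{n}" for n in g.nodes})
            for u, v in g.edges:
                g.edges[u, v]["abs_corr"] = float(rng.uniform(0.5, 1.0))
            membership = {n: int(rng.integers(1, 4)) for n in g.nodes}
            assert modularity(g, membership) == pytest.approx(
                brute_force_modularity(g, membership), abs=1e-12
            )

    def test_uncovered_node_rejected(self):
        g, _, _ = two_clique_graph()
        with pytest.raises(ValueError):
            modularity(g, {"L0": 1})

    def test_community_detection_on_toy_matches_hand_formula(self):
        # 7-node toy: triangle + square sharing nothing, one bridge
        g = nx.Graph()
        for u, v in [(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (5, 6), (6, 3), (2, 3)]:
            g.add_edge(f"A:{u}", f"A:{v}", abs_corr=1.0, weight=0.3)
        p = detect_communities(g)
        assert p.modularity == pytest.approx(
            brute_force_modularity(g, p.membership), abs=1e-12
        )


def exhaustive_k_shortest(graph, sources, sinks, k):
    """Enumerate every simple source→sink path and keep the k lightest."""
    found = []
    for s in sources:
        for t in sinks:
            if s not in graph or t not in graph:
                continue
            for p in nx.all_simple_paths(graph, s, t):
                w = sum(graph.edges[u, v]["weight"] for u, v in zip(p, p[1:]))
                found.append((w, p))
    found.sort(key=lambda item: item[0])
    return found[:k]


class TestSuboptimalPaths:
    def test_single_edge_graph(self):
        g = nx.Graph()
        g.add_edge("s", "t", weight=0.7, abs_corr=0.5)
        ens = suboptimal_paths(g, ["s"], ["t"], k=5)
        assert ens.paths == [["s", "t"]]
        assert ens.weights == [pytest.approx(0.7)]
        assert ens.node_usage == {"s": 1, "t": 1}

    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(12)
        g = nx.gnp_random_graph(6, 0.7, seed=7)
        for u, v in g.edges:
            g.edges[u, v]["weight"] = float(rng.uniform(0.1, 2.0))
        ens = suboptimal_paths(g, [0], [5], k=5)
        expected = exhaustive_k_shortest(g, [0], [5], 5)
        assert len(ens.paths) == len(expected)
        np.testing.assert_allclose(ens.weights, [w for w, _ in expected], atol=1e-12)
        assert ens.paths == [p for _, p in expected]

    def test_pooled_pairs_match_exhaustive(self):
        rng = np.random.default_rng(3)
        g = nx.gnp_random_graph(8, 0.5, seed=21)
        for u, v in g.edges:
            g.edges[u, v]["weight"] = float(rng.uniform(0.1, 2.0))
        sources, sinks = [0, 1], [6, 7]
        ens = suboptimal_paths(g, sources, sinks, k=10)
        expected = exhaustive_k_shortest(g, sources, sinks, 10)
        np.testing.assert_allclose(ens.weights, [w for w, _ in expected], atol=1e-12)

    def test_first_path_is_plain_shortest_path(self):
        rng = np.random.default_rng(5)
        g = nx.gnp_random_graph(9, 0.4, seed=9)
        for u, v in g.edges:
            g.edges[u, v]["weight"] = float(rng.uniform(0.1, 2.0))
        if nx.has_path(g, 0, 8):
            ens = suboptimal_paths(g, [0], [8], k=50)
            assert ens.paths[0] == nx.shortest_path(g, 0, 8, weight="weight")
            assert all(b >= a - 1e-12 for a, b in zip(ens.weights, ens.weights[1:]))

    def test_disconnected_status(self):
        g = nx.Graph()
        g.add_nodes_from(["s", "t"])
        ens = suboptimal_paths(g, ["s"], ["t"], k=3)
        assert ens.status == "disconnected"
        assert ens.paths == []

    def test_overlapping_source_sink_rejected(self):
        g = nx.Graph()
        g.add_edge("s", "t", weight=1.0)
        with pytest.raises(ValueError):
            suboptimal_paths(g, ["s"], ["s", "t"], k=3)
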