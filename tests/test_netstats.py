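"""Statistics against closed forms, brute-force enumeration, and networkx."""

from __future__ import annotations

from itertools import combinations, permutations

import networkx as nx
import numpy as np
import pytest

from collabnet import (
    RelationGraph,
    UndefinedStatisticError,
    betweenness,
    centralization,
    degree_stats,
    network_summary,
    node_stats,
    response_rate,
)
from conftest import brute_force_betweenness, make_graph, random_graph


def star(n: int) -> RelationGraph:
    return make_graph([f"v{i}" for i in range(n)],
                      [("v0", f"v{i}") for i in range(1, n)])


def complete(n: int) -> RelationGraph:
    nodes = [f"v{i}" for i in range(n)]
    return make_graph(nodes, combinations(nodes, 2))


def cycle(n: int) -> RelationGraph:
    nodes = [f"v{i}" for i in range(n)]
    return make_graph(nodes, [(nodes[i], nodes[(i + 1) % n]) for i in range(n)])


class TestDegree:
    def test_examples(self):
        g = star(5)
        deg = {r.agency_id: r.degree for r in degree_stats(g)}
        assert deg["v0"] == 4 and all(deg[f"v{i}"] == 1 for i in range(1, 5))
        iso = make_graph(["a", "b", "c"], [("a", "b")])
        assert {r.agency_id: r.degree for r in degree_stats(iso)}["c"] == 0

    def test_mutual_referral_counts_once_per_direction(self):
        g = make_graph(["a", "b", "c"], [("a", "b"), ("b", "a")], directed=True)
        rows = {r.agency_id: r for r in degree_stats(g)}
        assert rows["a"].in_degree == 1 and rows["a"].out_degree == 1

    def test_handshake_identities(self):
        rng = np.random.default_rng(42)
        for _ in range(30):
            g = random_graph(rng, int(rng.integers(3, 12)), rng.random())
            degs = [r.degree for r in degree_stats(g)]
            assert sum(degs) == 2 * g.n_edges
        for _ in range(30):
            n = int(rng.integers(3, 10))
            nodes = [f"v{i}" for i in range(n)]
            arcs = [(u, v) for u in nodes for v in nodes
                    if u != v and rng.random() < 0.3]
            g = make_graph(nodes, arcs, directed=True)
            rows = degree_stats(g)
            assert sum(r.in_degree for r in rows) == g.n_edges
            assert sum(r.out_degree for r in rows) == g.n_edges

    def test_adding_edge_never_decreases_degree(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            g = random_graph(rng, 8, 0.3)
            missing = [e for e in combinations(g.nodes, 2) if e not in g.edges]
            if not missing:
                continue
            extra = missing[int(rng.integers(len(missing)))]
            g2 = make_graph(g.nodes, list(g.edges) + [extra])
            d1 = {r.agency_id: r.degree for r in degree_stats(g)}
            d2 = {r.agency_id: r.degree for r in degree_stats(g2)}
            assert all(d2[v] >= d1[v] for v in g.nodes)


class TestBetweenness:
    def test_path_middle_node(self):
        g = make_graph(["a", "b", "c"], [("a", "b"), ("b", "c")])
        assert betweenness(g) == {"a": 0.0, "b": 1.0, "c": 0.0}

    def test_complete_graph_all_zero(self):
        assert set(betweenness(complete(4)).values()) == {0.0}

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_enumeration(self, seed):
        """Brandes accumulation equals explicit all-shortest-paths counting."""
        rng = np.random.default_rng(seed)
        for _ in range(10):
            n = int(rng.integers(2, 9))
            g = random_graph(rng, n, rng.uniform(0.1, 0.9))
            fast = betweenness(g)
            slow = brute_force_betweenness(g)
            assert fast == pytest.approx(slow, abs=1e-9)

    def test_matches_networkx_on_disconnected_graph(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            g = random_graph(rng, 12, 0.15)  # sparse: usually disconnected
            nxg = nx.Graph()
            nxg.add_nodes_from(g.nodes)
            nxg.add_edges_from(g.edges)
            oracle = nx.betweenness_centrality(nxg, normalized=False)
            assert betweenness(g) == pytest.approx(oracle, abs=1e-9)

    def test_directed_layer_rejected(self):
        g = make_graph(["a", "b"], [("a", "b")], directed=True)
        with pytest.raises(ValueError):
            betweenness(g)


def _numerator(scores) -> float:
    c = list(scores.values())
    return sum(max(c) - x for x in c)


class TestCentralization:
    @pytest.mark.parametrize("n", range(4, 11))
    def test_star_attains_one(self, n):
        g = star(n)
        deg = {r.agency_id: float(r.degree) for r in degree_stats(g)}
        assert centralization(deg, "degree_nondirected") == pytest.approx(1.0)
        assert centralization(
            betweenness(g), "betweenness_nondirected"
        ) == pytest.approx(1.0)

    @pytest.mark.parametrize("make", [complete, cycle], ids=["complete", "cycle"])
    def test_vertex_transitive_graphs_are_zero(self, make):
        g = make(6)
        deg = {r.agency_id: float(r.degree) for r in degree_stats(g)}
        assert centralization(deg, "degree_nondirected") == 0.0
        assert centralization(betweenness(g), "betweenness_nondirected") == 0.0

    def test_small_n_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            centralization({"a": 1.0, "b": 1.0}, "degree_nondirected")

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError, match="unknown centralization kind"):
            centralization({"a": 1.0, "b": 0.0, "c": 0.0}, "closeness")

    @pytest.mark.parametrize("n", [3, 4, 5])
    def test_exhaustive_undirected_maximum(self, n):
        """The normalizers equal the true maxima over every graph on n nodes."""
        nodes = [f"v{i}" for i in range(n)]
        pairs = list(combinations(nodes, 2))
        best_deg, best_btw = 0.0, 0.0
        for mask in range(2 ** len(pairs)):
            edges = [pairs[i] for i in range(len(pairs)) if mask >> i & 1]
            g = make_graph(nodes, edges)
            deg = {r.agency_id: float(r.degree) for r in degree_stats(g)}
            best_deg = max(best_deg, _numerator(deg))
            best_btw = max(best_btw, _numerator(betweenness(g)))
            # every graph's index must already be within [0, 1]
            assert 0.0 <= centralization(deg, "degree_nondirected") <= 1.0
        assert best_deg == (n - 1) * (n - 2)
        assert best_btw == pytest.approx((n - 1) ** 2 * (n - 2) / 2)

    @pytest.mark.parametrize("n", [3, 4])
    def test_exhaustive_directed_maximum(self, n):
        """In-, out-, and total-degree maxima over every directed graph on n nodes.

        The total-degree maximum 2(N-1)(N-2) is attained by the reciprocal
        star (all arcs to and from one center).
        """
        nodes = [f"v{i}" for i in range(n)]
        arcs = list(permutations(nodes, 2))
        best = {"in": 0.0, "out": 0.0, "total": 0.0}
        for mask in range(2 ** len(arcs)):
            chosen = [arcs[i] for i in range(len(arcs)) if mask >> i & 1]
            indeg = {v: 0.0 for v in nodes}
            outdeg = {v: 0.0 for v in nodes}
            for u, v in chosen:
                outdeg[u] += 1
                indeg[v] += 1
            total = {v: indeg[v] + outdeg[v] for v in nodes}
            best["in"] = max(best["in"], _numerator(indeg))
            best["out"] = max(best["out"], _numerator(outdeg))
            best["total"] = max(best["total"], _numerator(total))
        assert best["in"] == (n - 1) ** 2
        assert best["out"] == (n - 1) ** 2
        assert best["total"] == 2 * (n - 1) * (n - 2)

    def test_reciprocal_star_attains_total_degree_maximum(self):
        for n in range(3, 8):
            nodes = [f"v{i}" for i in range(n)]
            arcs = [("v0", v) for v in nodes[1:]] + [(v, "v0") for v in nodes[1:]]
            g = make_graph(nodes, arcs, directed=True)
            rows = degree_stats(g)
            total = {r.agency_id: float(r.in_degree + r.out_degree) for r in rows}
            assert centralization(total, "total_degree_directed") == pytest.approx(1.0)


class TestNetworkSummary:
    def test_average_degree_nondirected(self):
        rng = np.random.default_rng(5)
        g = random_graph(rng, 10, 0.35)
        row = network_summary(g)
        nxg = nx.Graph()
        nxg.add_nodes_from(g.nodes)
        nxg.add_edges_from(g.edges)
        oracle = sum(d for _, d in nxg.degree()) / nxg.number_of_nodes()
        assert row.average_degree == pytest.approx(oracle)
        assert row.average_degree == pytest.approx(2 * row.n_edges / row.n_nodes)

    def test_directed_conventions(self):
        g = make_graph(["a", "b", "c", "d"],
                       [("a", "b"), ("b", "a"), ("c", "a")], directed=True)
        row = network_summary(g)
        assert row.average_degree == pytest.approx(3 / 4)       # arcs per agency
        assert row.total_degree_mean == pytest.approx(6 / 4)    # in+out per agency
        assert row.degree_centralization is None
        assert row.betweenness_centralization is None
        assert row.in_degree_centralization is not None

    def test_edgeless_graph(self):
        g = make_graph(["a", "b", "c", "d"], [])
        row = network_summary(g)
        assert row.average_degree == 0.0
        assert row.degree_centralization == 0.0
        assert row.betweenness_centralization == 0.0
        assert row.n_isolates == 4

    def test_empty_node_set_rejected(self):
        with pytest.raises(ValueError):
            network_summary(make_graph([], []))

    def test_node_stats_include_betweenness(self):
        g = make_graph(["a", "b", "c"], [("a", "b"), ("b", "c")])
        rows = {r.agency_id: r for r in node_stats(g)}
        assert rows["b"].betweenness == 1.0 and rows["b"].degree == 2


class TestResponseRate:
    @pytest.mark.parametrize(
        "completed,invited,expected",
        [(152, 182, 83.5), (10, 10, 100.0), (821, 1000, 82.1), (1, 3, 33.3)],
    )
    def test_rounded_percentages(self, completed, invited, expected):
        assert response_rate(completed, invited) == expected

    def test_half_up_rounding(self):
        assert response_rate(125, 1000) == 12.5
        assert response_rate(845, 1000) == 84.5

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            response_rate(5, 0)
        with pytest.raises(ValueError):
            response_rate(11, 10)

    def test_individual_and_agency_rates_together(self):
        from collabnet import response_rates

        rates = response_rates(182, 152, 158, 142)
        assert rates["individual"] == 83.5
        assert rates["agency"] == 89.9
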