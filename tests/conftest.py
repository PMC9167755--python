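"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pytest

from collabnet import Agency, AgencyType, GeneratorConfig, RelationGraph
from collabnet.types import undirected_edge


def small_config(seed: int = 0, n_areas: int = 2,
                 size: tuple[int, int] = (12, 16), **overrides) -> GeneratorConfig:
    """A feasible generator config small enough for fast tests."""
    kwargs = dict(
        n_areas=n_areas,
        agencies_per_area=size,
        target_avg_degree={
            "contact": 6.0,
            "exchange_info": 4.5,
            "promote": 3.5,
            "events": 3.0,
            "develop_sustain": 2.5,
            "share_resources": 2.0,
            "referral": 2.5,
        },
        seed=seed,
    )
    kwargs.update(overrides)
    return GeneratorConfig(**kwargs)


def make_graph(nodes, edges, directed: bool = False,
               relationship: str = "exchange_info") -> RelationGraph:
    nodes = tuple(nodes)
    if directed:
        es = frozenset(tuple(e) for e in edges)
    else:
        es = frozenset(undirected_edge(u, v) for u, v in edges)
    return RelationGraph(
        relationship="referral" if directed else relationship,
        directed=directed, nodes=nodes, edges=es,
    )


def random_graph(rng: np.random.Generator, n: int, p: float) -> RelationGraph:
    nodes = [f"v{i}" for i in range(n)]
    edges = [e for e in combinations(nodes, 2) if rng.random() < p]
    return make_graph(nodes, edges)


def brute_force_betweenness(graph: RelationGraph) -> dict[str, float]:
    """Independent oracle: explicit enumeration of every shortest path.

    For each unordered pair, BFS gives distances and predecessor lists; all
    geodesics are then enumerated by backward depth-first traversal and each
    interior node receives 1/(number of geodesics) per path it lies on.
    """
    assert not graph.directed
    adj = graph.adjacency()
    nodes = list(graph.nodes)
    bc = {v: 0.0 for v in nodes}
    for i, s in enumerate(nodes):
        dist = {s: 0}
        preds: dict[str, list[str]] = {v: [] for v in nodes}
        frontier = [s]
        while frontier:
            nxt = []
            for v in frontier:
                for w in adj[v]:
                    if w not in dist:
                        dist[w] = dist[v] + 1
                        nxt.append(w)
                    if dist[w] == dist[v] + 1:
                        preds[w].append(v)
            frontier = nxt
        for t in nodes[i + 1:]:
            if t not in dist:
                continue  # unreachable pair contributes nothing

            def paths_to(v):
                if v == s:
                    return [[s]]
                return [p + [v] for u in preds[v] for p in paths_to(u)]

            geodesics = paths_to(t)
            credit = 1.0 / len(geodesics)
            for path in geodesics:
                for inner in path[1:-1]:
                    bc[inner] += credit
    return bc


@pytest.fixture
def tiny_roster() -> list[Agency]:
    return [
        Agency(f"A{i}", f"Agency {i}", t, "area1")
        for i, t in enumerate(
            [AgencyType.FQHC, AgencyType.LHD, AgencyType.SCHOOL,
             AgencyType.COMMUNITY_PARTNER, AgencyType.HEALTHCARE_FACILITY],
            start=1,
        )
    ]
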