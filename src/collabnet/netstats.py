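"""Node- and network-level statistics, implemented from first principles.

Nothing here calls a graph library: degree counting, Brandes' shortest-path
betweenness accumulation, and Freeman-style centralization indices are all
computed directly on the layer's edge set.  Graph libraries appear only as
independent oracles in the test suite.

Conventions (matching the usual sociometric defaults):

* Betweenness is raw (unnormalized), over unordered pairs, on nondirected
  layers; pairs with no connecting path contribute nothing; equal-length
  shortest paths split credit equally.
* Centralization is Σᵢ (c_max − cᵢ) normalized by the maximum that sum can
  attain over any graph on the same number of nodes: (N−1)(N−2) for
  nondirected degree, (N−1)² for in- and for out-degree, 2(N−1)(N−2) for
  directed total degree, and (N−1)²(N−2)/2 for raw nondirected betweenness.
  The nondirected maxima are attained by the star; the directed total-degree
  maximum by the reciprocal star (every arc to and from the center).
* Isolates stay in N: a disconnected layer is summarized over its full
  roster.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Optional

from .types import ContactLevel, RelationGraph, UndefinedStatisticError

CENTRALIZATION_KINDS = (
    "degree_nondirected",
    "in_degree",
    "out_degree",
    "total_degree_directed",
    "betweenness_nondirected",
)


@dataclass
class NodeStatRow:
    """Per-agency statistics for one layer."""

    agency_id: str
    degree: Optional[int] = None
    in_degree: Optional[int] = None
    out_degree: Optional[int] = None
    betweenness: Optional[float] = None


@dataclass
class NetworkStatRow:
    """Whole-network statistics for one layer.

    ``average_degree`` is 2E/N for nondirected layers and E/N (each arc
    counted once) for directed layers; directed layers also carry
    ``total_degree_mean`` = 2E/N since both conventions appear in practice.
    Centralizations are ``None`` when undefined (N < 3, or the wrong
    directedness for the index).
    """

    relationship: str
    directed: bool
    contact_threshold: Optional[str]
    n_nodes: int
    n_edges: int
    n_isolates: int
    average_degree: float
    total_degree_mean: Optional[float] = None
    degree_centralization: Optional[float] = None
    betweenness_centralization: Optional[float] = None
    in_degree_centralization: Optional[float] = None
    out_degree_centralization: Optional[float] = None
    total_degree_centralization: Optional[float] = None
    area_id: Optional[str] = None


def degree_stats(graph: RelationGraph) -> list[NodeStatRow]:
    """Degree per node: plain degree for nondirected layers, in/out for directed.

    Bidirectional referral partners count once per direction, so a mutual
    referral partner contributes 1 to in-degree and 1 to out-degree.
    """
    if graph.directed:
        indeg = {v: 0 for v in graph.nodes}
        outdeg = {v: 0 for v in graph.nodes}
        for u, v in graph.edges:
            outdeg[u] += 1
            indeg[v] += 1
        return [
            NodeStatRow(agency_id=v, in_degree=indeg[v], out_degree=outdeg[v])
            for v in graph.nodes
        ]
    deg = {v: 0 for v in graph.nodes}
    for u, v in graph.edges:
        deg[u] += 1
        deg[v] += 1
    return [NodeStatRow(agency_id=v, degree=deg[v]) for v in graph.nodes]


def betweenness(graph: RelationGraph) -> dict[str, float]:
    """Raw shortest-path betweenness on a nondirected (possibly disconnected) layer.

    Brandes' dependency accumulation: one BFS per source builds the
    shortest-path DAG with geodesic counts sigma, then dependencies are
    accumulated from the leaves inward.  Summing over all sources counts
    each unordered pair twice, so the total is halved.
    """
    if graph.directed:
        raise ValueError("betweenness is computed for nondirected layers only")
    adj = graph.adjacency()
    bc = {v: 0.0 for v in graph.nodes}
    for s in graph.nodes:
        stack: list[str] = []
        pred: dict[str, list[str]] = {v: [] for v in graph.nodes}
        sigma = {v: 0.0 for v in graph.nodes}
        dist = {v: -1 for v in graph.nodes}
        sigma[s] = 1.0
        dist[s] = 0
        queue = [s]
        head = 0
        while head < len(queue):
            v = queue[head]
            head += 1
            stack.append(v)
            for w in adj[v]:
                if dist[w] < 0:
                    dist[w] = dist[v] + 1
                    queue.append(w)
                if dist[w] == dist[v] + 1:
                    sigma[w] += sigma[v]
                    pred[w].append(v)
        delta = {v: 0.0 for v in graph.nodes}
        while stack:
            w = stack.pop()
            for v in pred[w]:
                delta[v] += (sigma[v] / sigma[w]) * (1.0 + delta[w])
            if w != s:
                bc[w] += delta[w]
    return {v: b / 2.0 for v, b in bc.items()}


def _max_numerator(kind: str, n: int) -> float:
    if kind == "degree_nondirected":
        return float((n - 1) * (n - 2))
    if kind in ("in_degree", "out_degree"):
        return float((n - 1) ** 2)
    if kind == "total_degree_directed":
        return float(2 * (n - 1) * (n - 2))
    if kind == "betweenness_nondirected":
        return (n - 1) ** 2 * (n - 2) / 2.0
    raise ValueError(
        f"unknown centralization kind {kind!r}; allowed: "
        f"{', '.join(CENTRALIZATION_KINDS)}"
    )


def centralization(scores: Mapping[str, float], kind: str) -> float:
    """Freeman centralization of a centrality score vector, in [0, 1].

    Σᵢ (c_max − cᵢ) divided by the maximum that sum attains over any graph
    with the same number of nodes (see module docstring for the maxima).
    """
    n = len(scores)
    if n < 3:
        raise UndefinedStatisticError(
            f"centralization undefined for N={n} (< 3): denominator vanishes"
        )
    denom = _max_numerator(kind, n)
    c_max = max(scores.values())
    num = sum(c_max - c for c in scores.values())
    return num / denom


def network_summary(graph: RelationGraph, area_id: Optional[str] = None) -> NetworkStatRow:
    """All applicable network-level statistics for one layer."""
    n = graph.n_nodes
    if n == 0:
        raise ValueError("cannot summarize a graph with no nodes")
    e = graph.n_edges
    n_isolates = len(graph.isolates())
    threshold = (
        graph.contact_threshold.label
        if isinstance(graph.contact_threshold, ContactLevel)
        else graph.contact_threshold
    )
    row = NetworkStatRow(
        relationship=graph.relationship,
        directed=graph.directed,
        contact_threshold=threshold,
        n_nodes=n,
        n_edges=e,
        n_isolates=n_isolates,
        average_degree=(e / n) if graph.directed else (2.0 * e / n),
        area_id=area_id,
    )
    stats = degree_stats(graph)
    if graph.directed:
        row.total_degree_mean = 2.0 * e / n
        if n >= 3:
            indeg = {s.agency_id: float(s.in_degree) for s in stats}
            outdeg = {s.agency_id: float(s.out_degree) for s in stats}
            total = {
                s.agency_id: float(s.in_degree + s.out_degree) for s in stats
            }
            row.in_degree_centralization = centralization(indeg, "in_degree")
            row.out_degree_centralization = centralization(outdeg, "out_degree")
            row.total_degree_centralization = centralization(
                total, "total_degree_directed"
            )
    else:
        if n >= 3:
            deg = {s.agency_id: float(s.degree) for s in stats}
            row.degree_centralization = centralization(deg, "degree_nondirected")
            row.betweenness_centralization = centralization(
                betweenness(graph), "betweenness_nondirected"
            )
    return row


def node_stats(graph: RelationGraph) -> list[NodeStatRow]:
    """Per-node statistics for one layer (degree + betweenness, or in/out)."""
    rows = degree_stats(graph)
    if not graph.directed:
        bc = betweenness(graph)
        for r in rows:
            r.betweenness = bc[r.agency_id]
    return rows


def response_rates(
    invited_individuals: int,
    completed: int,
    invited_agencies: int,
    responding_agencies: int,
) -> dict[str, float]:
    """Individual and agency response rates, each rounded to one decimal."""
    return {
        "individual": response_rate(completed, invited_individuals),
        "agency": response_rate(responding_agencies, invited_agencies),
    }


def response_rate(completed: int, invited: int) -> float:
    """Percentage response rate, rounded half-up to one decimal place."""
    if invited <= 0:
        raise ValueError("invited count must be positive")
    if completed < 0 or completed > invited:
        raise ValueError("completed must be between 0 and invited")
    pct = Decimal(completed * 100) / Decimal(invited)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))
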