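"""Cross-area summaries, node-vs-average comparisons, and dissemination outputs.

Two dissemination artifacts are produced: a *navigator bundle* — a
self-contained, schema-validated JSON document per service area carrying
every layer's node list (with statistics, deltas against the network
average, and seeded force-directed layout coordinates), edge list, and
network-statistic table, ready for any interactive front end — and a static
per-area markdown infographic report with the cross-area summary table,
top-ranked agencies, isolates, and response-rate line.

All presentation rounding happens at render time only; summaries are
computed and stored at full precision.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np
from pydantic import BaseModel, ConfigDict

from .netstats import NetworkStatRow, NodeStatRow, network_summary, node_stats
from .reconcile import LAYER_KEYS
from .types import ACTIVITIES, ACTIVITY_TITLES, ContactLevel, RelationGraph

PathLike = Union[str, Path]

SCHEMA_VERSION = "1.0"

#: Statistics summarized across areas, per layer directedness.
_NONDIRECTED_STATS = ("average_degree", "degree_centralization", "betweenness_centralization")
_DIRECTED_STATS = (
    "average_degree",
    "in_degree_centralization",
    "out_degree_centralization",
    "total_degree_centralization",
)


@dataclass
class AreaSummary:
    """Mean and sample SD of one statistic for one layer, across areas."""

    relationship: str
    contact_threshold: Optional[str]
    statistic: str
    mean: float
    sd: Optional[float]  # None (undefined) when only one area
    n_areas: int


def summarize_across_areas(rows: Sequence[NetworkStatRow]) -> list[AreaSummary]:
    """Cross-area mean and sample standard deviation per layer per statistic.

    The SD uses the n−1 denominator (areas are a sample of service areas);
    with a single area the SD is flagged undefined (``None``).
    """
    groups: dict[tuple[str, Optional[str]], list[NetworkStatRow]] = {}
    for row in rows:
        groups.setdefault((row.relationship, row.contact_threshold), []).append(row)

    out: list[AreaSummary] = []
    for (rel, thr), members in groups.items():
        stats = _DIRECTED_STATS if members[0].directed else _NONDIRECTED_STATS
        for stat in stats:
            values = [getattr(m, stat) for m in members if getattr(m, stat) is not None]
            if not values:
                continue
            n = len(values)
            mean = sum(values) / n
            if n >= 2:
                sd = math.sqrt(sum((v - mean) ** 2 for v in values) / (n - 1))
            else:
                sd = None
            out.append(
                AreaSummary(
                    relationship=rel,
                    contact_threshold=thr,
                    statistic=stat,
                    mean=mean,
                    sd=sd,
                    n_areas=n,
                )
            )
    return out


def node_vs_average(node_rows: Sequence[NodeStatRow]) -> dict[str, dict[str, float]]:
    """Per-agency deltas of each statistic against its mean over nodes.

    Returned as ``{agency_id: {statistic: node_value - mean}}``; deltas of
    any one statistic sum to zero over the nodes by construction.
    """
    if not node_rows:
        return {}
    stats = [
        s
        for s in ("degree", "in_degree", "out_degree", "betweenness")
        if getattr(node_rows[0], s) is not None
    ]
    means = {
        s: sum(getattr(r, s) for r in node_rows) / len(node_rows) for s in stats
    }
    return {
        r.agency_id: {s: getattr(r, s) - means[s] for s in stats}
        for r in node_rows
    }


# ---------------------------------------------------------------------------
# seeded force-directed layout
# ---------------------------------------------------------------------------


def fr_layout(
    graph: RelationGraph, seed: int, iterations: int = 60
) -> dict[str, tuple[float, float]]:
    """Fruchterman–Reingold layout with a fixed iteration count and seed.

    Positions start from a seeded uniform draw in the unit square and are
    relaxed with the standard repulsive k²/d and attractive d²/k forces
    under a linearly cooling temperature, so the result is a pure function
    of (graph, seed).
    """
    nodes = list(graph.nodes)
    n = len(nodes)
    if n == 0:
        return {}
    rng = np.random.default_rng(np.random.SeedSequence([seed, n]))
    pos = rng.random((n, 2)) * 2.0 - 1.0
    if n == 1:
        return {nodes[0]: (float(pos[0, 0]), float(pos[0, 1]))}
    index = {v: i for i, v in enumerate(nodes)}
    # undirected incidence for layout purposes
    edge_idx = np.array(
        sorted({tuple(sorted((index[u], index[v]))) for u, v in graph.edges}),
        dtype=int,
    ).reshape(-1, 2)
    k = math.sqrt(1.0 / n)
    t = 0.1
    dt = t / (iterations + 1)
    for _ in range(iterations):
        delta = pos[:, None, :] - pos[None, :, :]
        dist = np.linalg.norm(delta, axis=-1)
        np.clip(dist, 0.01, None, out=dist)
        force = (k * k) / (dist * dist)  # repulsion
        np.fill_diagonal(force, 0.0)
        disp = (delta * force[..., None]).sum(axis=1)
        if len(edge_idx):
            d = pos[edge_idx[:, 0]] - pos[edge_idx[:, 1]]
            dn = np.linalg.norm(d, axis=-1, keepdims=True)
            dn = np.clip(dn, 0.01, None)
            pull = d * dn / k
            np.add.at(disp, edge_idx[:, 0], -pull)
            np.add.at(disp, edge_idx[:, 1], pull)
        length = np.linalg.norm(disp, axis=-1, keepdims=True)
        length = np.clip(length, 1e-12, None)
        pos += disp / length * np.minimum(length, t)
        t -= dt
    return {v: (float(pos[i, 0]), float(pos[i, 1])) for v, i in index.items()}


# ---------------------------------------------------------------------------
# navigator bundle (pydantic schema; exported JSON schema is shipped in repo)
# ---------------------------------------------------------------------------


class BundleNode(BaseModel):
    model_config = ConfigDict(extra="forbid")

    id: str
    name: str = ""
    agency_type: str = ""
    degree: Optional[int] = None
    in_degree: Optional[int] = None
    out_degree: Optional[int] = None
    betweenness: Optional[float] = None
    vs_avg_degree: Optional[float] = None
    vs_avg_betweenness: Optional[float] = None
    vs_avg_in_degree: Optional[float] = None
    vs_avg_out_degree: Optional[float] = None
    x: float
    y: float


class BundleEdge(BaseModel):
    model_config = ConfigDict(extra="forbid")

    source: str
    target: str
    contact_level: Optional[str] = None
    bidirectional: Optional[bool] = None


class BundleNetworkStats(BaseModel):
    model_config = ConfigDict(extra="forbid")

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


class BundleLayer(BaseModel):
    model_config = ConfigDict(extra="forbid")

    key: str
    relationship: str
    contact_threshold: Optional[str] = None
    directed: bool
    nodes: list[BundleNode]
    edges: list[BundleEdge]
    network: BundleNetworkStats


class NavigatorBundle(BaseModel):
    model_config = ConfigDict(extra="forbid")

    schema_version: str
    area_id: str
    seed: int
    layers: list[BundleLayer]


def _layer_payload(graph: RelationGraph, key: str, seed: int, layer_seed: int) -> BundleLayer:
    rows = node_stats(graph)
    deltas = node_vs_average(rows)
    layout = fr_layout(graph, layer_seed)
    net = network_summary(graph)
    nodes = []
    for r in rows:
        meta = graph.node_meta.get(r.agency_id, {})
        d = deltas.get(r.agency_id, {})
        x, y = layout[r.agency_id]
        nodes.append(
            BundleNode(
                id=r.agency_id,
                name=str(meta.get("name", "")),
                agency_type=str(meta.get("agency_type", "")),
                degree=r.degree,
                in_degree=r.in_degree,
                out_degree=r.out_degree,
                betweenness=r.betweenness,
                vs_avg_degree=d.get("degree"),
                vs_avg_betweenness=d.get("betweenness"),
                vs_avg_in_degree=d.get("in_degree"),
                vs_avg_out_degree=d.get("out_degree"),
                x=x,
                y=y,
            )
        )
    bidir = graph.bidirectional_pairs()
    edges = []
    for u, v in sorted(graph.edges):
        lvl = graph.edge_levels.get((u, v))
        edges.append(
            BundleEdge(
                source=u,
                target=v,
                contact_level=lvl.label if lvl is not None else None,
                bidirectional=(
                    ((u, v) if u < v else (v, u)) in bidir if graph.directed else None
                ),
            )
        )
    return BundleLayer(
        key=key,
        relationship=graph.relationship,
        contact_threshold=net.contact_threshold,
        directed=graph.directed,
        nodes=nodes,
        edges=edges,
        network=BundleNetworkStats(
            n_nodes=net.n_nodes,
            n_edges=net.n_edges,
            n_isolates=net.n_isolates,
            average_degree=net.average_degree,
            total_degree_mean=net.total_degree_mean,
            degree_centralization=net.degree_centralization,
            betweenness_centralization=net.betweenness_centralization,
            in_degree_centralization=net.in_degree_centralization,
            out_degree_centralization=net.out_degree_centralization,
            total_degree_centralization=net.total_degree_centralization,
        ),
    )


def build_navigator_bundle(
    area_id: str, layers: Mapping[str, RelationGraph], seed: int
) -> NavigatorBundle:
    """Assemble the complete per-area bundle (all ten layers required)."""
    missing = [k for k in LAYER_KEYS if k not in layers]
    if missing:
        raise ValueError(f"missing layers: {', '.join(missing)}")
    return NavigatorBundle(
        schema_version=SCHEMA_VERSION,
        area_id=area_id,
        seed=seed,
        layers=[
            _layer_payload(layers[key], key, seed, layer_seed=seed * 1000 + i)
            for i, key in enumerate(LAYER_KEYS)
        ],
    )


def bundle_to_json(bundle: NavigatorBundle) -> str:
    return json.dumps(bundle.model_dump(mode="json"), sort_keys=True, indent=1)


def write_bundle(bundle: NavigatorBundle, path: PathLike) -> None:
    Path(path).write_text(bundle_to_json(bundle), encoding="utf-8")


def load_bundle(path: PathLike) -> NavigatorBundle:
    """Read a bundle back, validating it against the schema."""
    return NavigatorBundle.model_validate(
        json.loads(Path(path).read_text(encoding="utf-8"))
    )


def write_layer_json(graph: RelationGraph, path: PathLike, seed: int = 0) -> None:
    """Single-layer navigator JSON (same layer schema as the full bundle)."""
    key = (
        f"contact_{graph.contact_threshold.label}"
        if isinstance(graph.contact_threshold, ContactLevel)
        else graph.relationship
    )
    layer = _layer_payload(graph, key, seed, layer_seed=seed)
    Path(path).write_text(
        json.dumps(layer.model_dump(mode="json"), sort_keys=True, indent=1),
        encoding="utf-8",
    )


# ---------------------------------------------------------------------------
# static infographic report
# ---------------------------------------------------------------------------


def _fmt(value: Optional[float], places: int) -> str:
    return "—" if value is None else f"{value:.{places}f}"


def render_summary_table(summaries: Sequence[AreaSummary]) -> str:
    """Markdown table of activity-layer statistics summarized across areas."""
    by_key: dict[tuple[str, str], AreaSummary] = {
        (s.relationship, s.statistic): s for s in summaries if s.contact_threshold is None
    }
    lines = [
        "| Activity | Average degree (mean) | (SD) | Degree centralization (mean) "
        "| (SD) | Betweenness centralization (mean) | (SD) |",
        "|---|---|---|---|---|---|---|",
    ]
    for act in ACTIVITIES:
        cells = [ACTIVITY_TITLES[act]]
        for stat, places in (
            ("average_degree", 1),
            ("degree_centralization", 3),
            ("betweenness_centralization", 3),
        ):
            s = by_key.get((act, stat))
            cells.append(_fmt(s.mean if s else None, places))
            cells.append(_fmt(s.sd if s else None, places))
        lines.append("| " + " | ".join(cells) + " |")
    return "\n".join(lines)


def _top_k(rows: Sequence[NodeStatRow], stat: str, k: int = 3) -> list[NodeStatRow]:
    """Top-k by a statistic; ties at the cut are all included (k may be exceeded)."""
    scored = sorted(
        (r for r in rows if getattr(r, stat) is not None),
        key=lambda r: (-getattr(r, stat), r.agency_id),
    )
    if len(scored) <= k:
        return scored
    cut = getattr(scored[k - 1], stat)
    return [r for r in scored if getattr(r, stat) >= cut]


def render_infographic(
    area_id: str,
    layers: Mapping[str, RelationGraph],
    summaries: Sequence[AreaSummary],
    response_rate_pct: Optional[float] = None,
    top_k: int = 3,
) -> str:
    """Per-area markdown report: summary table, top agencies, isolates."""
    lines = [f"# Network report — {area_id}", ""]
    if response_rate_pct is not None:
        lines += [f"Agency survey response rate: {response_rate_pct:.1f}%", ""]
    lines += ["## Activity networks across service areas", "",
              render_summary_table(summaries), ""]
    lines += [f"## Layers in {area_id}", ""]
    for key in LAYER_KEYS:
        graph = layers[key]
        title = ACTIVITY_TITLES.get(key, key.replace("_", " "))
        lines.append(f"### {title}")
        if graph.n_edges == 0:
            lines += ["", "no connections reported", ""]
            continue
        rows = node_stats(graph)
        net = network_summary(graph)
        lines.append("")
        lines.append(
            f"{net.n_nodes} agencies, {net.n_edges} "
            f"{'referral links' if graph.directed else 'ties'}, "
            f"average degree {net.average_degree:.1f}"
        )
        if graph.directed:
            ranked = _top_k(rows, "in_degree", top_k)
            lines.append(
                "Top by in-degree: "
                + ", ".join(f"{r.agency_id} ({r.in_degree})" for r in ranked)
            )
            ranked = _top_k(rows, "out_degree", top_k)
            lines.append(
                "Top by out-degree: "
                + ", ".join(f"{r.agency_id} ({r.out_degree})" for r in ranked)
            )
        else:
            ranked = _top_k(rows, "degree", top_k)
            lines.append(
                "Top by degree: "
                + ", ".join(f"{r.agency_id} ({r.degree})" for r in ranked)
            )
            ranked = _top_k(rows, "betweenness", top_k)
            lines.append(
                "Top by betweenness: "
                + ", ".join(f"{r.agency_id} ({r.betweenness:.1f})" for r in ranked)
            )
        isolates = graph.isolates()
        if isolates:
            lines.append(f"Not connected ({len(isolates)}): " + ", ".join(isolates))
        lines.append("")
    return "\n".join(lines)
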