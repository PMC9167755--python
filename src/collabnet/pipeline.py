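"""End-to-end orchestration: simulate fixtures, analyze a survey dataset.

The pipeline is deterministic: all randomness flows from the run seed, and
each run writes a manifest recording the seed and a hash of the effective
configuration so outputs can be reproduced bit for bit.
"""

from __future__ import annotations

import csv
import dataclasses
import hashlib
import json
import logging
from pathlib import Path
from typing import Optional, Sequence, Union

from . import io as cio
from .netstats import NetworkStatRow, network_summary, node_stats, response_rate
from .reconcile import LAYER_KEYS, ContactFallback, build_area_layers
from .report import (
    AreaSummary,
    build_navigator_bundle,
    node_vs_average,
    render_infographic,
    summarize_across_areas,
    write_bundle,
)
from .synthetic import (
    GeneratorConfig,
    generate_roster,
    generate_survey_responses,
    generate_true_networks,
    truth_layers,
)
from .types import Agency, DyadReport, RelationGraph

logger = logging.getLogger("collabnet.pipeline")

PathLike = Union[str, Path]


def config_hash(config: GeneratorConfig) -> str:
    """Stable hash of the effective generator configuration."""
    payload = dataclasses.asdict(config)
    payload["type_mix"] = {k.value: v for k, v in config.type_mix.items()}
    payload["contact_level_mix"] = {
        k.label: v for k, v in config.contact_level_mix.items()
    }
    blob = json.dumps(payload, sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()


def run_simulate(config: GeneratorConfig, out_dir: PathLike) -> dict:
    """Generate a synthetic dataset and write it (with planted truth) to disk."""
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    roster = generate_roster(config)
    truth = generate_true_networks(roster, config)
    reports = generate_survey_responses(truth, roster, config)

    cio.write_roster(roster, out / "roster.csv")
    cio.write_responses(reports, out / "responses.csv")
    truth_dir = out / "truth"
    truth_dir.mkdir(exist_ok=True)
    for area_id, area in truth.areas.items():
        for key, graph in truth_layers(area).items():
            cio.write_graph(graph, truth_dir / f"{area_id}_{key}.graphml", "graphml")

    manifest = {
        "command": "simulate",
        "seed": config.seed,
        "config_hash": config_hash(config),
        "n_areas": len(truth.areas),
        "n_agencies": len(roster),
        "n_reports": len(reports),
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True), encoding="utf-8"
    )
    return manifest


@dataclasses.dataclass
class AreaResult:
    area_id: str
    agencies: list[Agency]
    layers: dict[str, RelationGraph]
    network_rows: list[NetworkStatRow]


@dataclasses.dataclass
class AnalysisResult:
    areas: dict[str, AreaResult]
    summaries: list[AreaSummary]
    dropped_cross_area: int


def analyze_reports(
    roster: Sequence[Agency],
    reports: Sequence[DyadReport],
    fallback: ContactFallback = "reported",
) -> AnalysisResult:
    """Reconcile reports per service area and compute all statistics.

    Reports whose partner belongs to a different service area are dropped
    with a logged count: each area's network is analyzed separately.
    """
    area_of = {a.agency_id: a.area_id for a in roster}
    by_area_agencies: dict[str, list[Agency]] = {}
    for a in roster:
        by_area_agencies.setdefault(a.area_id, []).append(a)

    by_area_reports: dict[str, list[DyadReport]] = {aid: [] for aid in by_area_agencies}
    dropped = 0
    for r in reports:
        if area_of[r.reporter_agency_id] != area_of[r.partner_agency_id]:
            dropped += 1
            continue
        by_area_reports[area_of[r.reporter_agency_id]].append(r)
    if dropped:
        logger.warning("dropped %d cross-area report row(s)", dropped)

    areas: dict[str, AreaResult] = {}
    all_rows: list[NetworkStatRow] = []
    for area_id, agencies in by_area_agencies.items():
        layers = build_area_layers(by_area_reports[area_id], agencies, fallback=fallback)
        rows = [network_summary(g, area_id=area_id) for g in layers.values()]
        all_rows.extend(rows)
        areas[area_id] = AreaResult(
            area_id=area_id, agencies=agencies, layers=layers, network_rows=rows
        )
    return AnalysisResult(
        areas=areas,
        summaries=summarize_across_areas(all_rows),
        dropped_cross_area=dropped,
    )


def _write_network_stats_csv(result: AnalysisResult, path: Path) -> None:
    fields = [
        "area_id", "relationship", "contact_threshold", "directed", "n_nodes",
        "n_edges", "n_isolates", "average_degree", "total_degree_mean",
        "degree_centralization", "betweenness_centralization",
        "in_degree_centralization", "out_degree_centralization",
        "total_degree_centralization",
    ]
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(fields)
        for area in result.areas.values():
            for row in area.network_rows:
                w.writerow(["" if getattr(row, f) is None else getattr(row, f)
                            for f in fields])


def _write_node_stats_csv(result: AnalysisResult, path: Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(
            ["area_id", "layer", "agency_id", "degree", "in_degree", "out_degree",
             "betweenness", "vs_avg_degree", "vs_avg_betweenness",
             "vs_avg_in_degree", "vs_avg_out_degree"]
        )
        for area in result.areas.values():
            for key in LAYER_KEYS:
                rows = node_stats(area.layers[key])
                deltas = node_vs_average(rows)
                for r in rows:
                    d = deltas.get(r.agency_id, {})
                    def cell(v):
                        return "" if v is None else v
                    w.writerow(
                        [area.area_id, key, r.agency_id, cell(r.degree),
                         cell(r.in_degree), cell(r.out_degree), cell(r.betweenness),
                         cell(d.get("degree")), cell(d.get("betweenness")),
                         cell(d.get("in_degree")), cell(d.get("out_degree"))]
                    )


def _write_summary_csv(summaries: Sequence[AreaSummary], path: Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["relationship", "contact_threshold", "statistic", "mean", "sd",
                    "n_areas"])
        for s in summaries:
            w.writerow(
                [s.relationship, s.contact_threshold or "", s.statistic, s.mean,
                 "" if s.sd is None else s.sd, s.n_areas]
            )


def run_analyze(
    roster_path: PathLike,
    responses_path: PathLike,
    out_dir: PathLike,
    strict: bool = True,
    contact_fallback: ContactFallback = "reported",
    seed: int = 0,
    write_graphs: bool = True,
    write_bundles: bool = True,
    write_report: bool = True,
) -> AnalysisResult:
    """Full analysis run: read, reconcile, compute, summarize, write outputs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    roster = cio.read_roster(roster_path)
    reports = cio.read_responses(responses_path, roster, strict=strict)
    result = analyze_reports(roster, reports, fallback=contact_fallback)

    _write_network_stats_csv(result, out / "network_stats.csv")
    _write_node_stats_csv(result, out / "node_stats.csv")
    _write_summary_csv(result.summaries, out / "summary.csv")

    responding = {r.reporter_agency_id for r in reports}
    for area_id, area in result.areas.items():
        if write_graphs:
            gdir = out / area_id / "graphs"
            gdir.mkdir(parents=True, exist_ok=True)
            for key, graph in area.layers.items():
                cio.write_graph(graph, gdir / f"{key}.graphml", "graphml")
                cio.write_graph(graph, gdir / f"{key}.csv", "edgelist_csv")
        if write_bundles:
            bdir = out / "bundles"
            bdir.mkdir(exist_ok=True)
            write_bundle(
                build_navigator_bundle(area_id, area.layers, seed=seed),
                bdir / f"{area_id}.json",
            )
        if write_report:
            rdir = out / "reports"
            rdir.mkdir(exist_ok=True)
            n_agencies = len(area.agencies)
            n_responding = sum(
                1 for a in area.agencies if a.agency_id in responding
            )
            rate = response_rate(n_responding, n_agencies) if n_agencies else None
            (rdir / f"{area_id}.md").write_text(
                render_infographic(
                    area_id, area.layers, result.summaries, response_rate_pct=rate
                ),
                encoding="utf-8",
            )

    manifest = {
        "command": "analyze",
        "seed": seed,
        "strict": strict,
        "contact_fallback": contact_fallback,
        "n_areas": len(result.areas),
        "n_reports": len(reports),
        "dropped_cross_area": result.dropped_cross_area,
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True), encoding="utf-8"
    )
    return result
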