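"""Readers and writers for every format the pipeline touches.

Tabular inputs (roster, survey responses) are RFC-4180 CSV read through
pandas and validated row by row — every malformed input yields a diagnostic
naming the row and field, never a silent coercion.  Graph layers are written
as GraphML (with node and edge attributes), edge-list CSV, or a
single-layer navigator JSON payload; GraphML has a matching reader so the
write-then-read round trip is identity.
"""

from __future__ import annotations

import csv
import logging
import xml.etree.ElementTree as ET
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd

from .types import (
    ACTIVITIES,
    Agency,
    AgencyType,
    ContactLevel,
    DyadReport,
    RelationGraph,
    ValidationError,
)

logger = logging.getLogger("collabnet.io")

PathLike = Union[str, Path]

ROSTER_COLUMNS = ("agency_id", "name", "agency_type", "area_id")
RESPONSE_COLUMNS = (
    "respondent_id",
    "reporter_agency_id",
    "partner_agency_id",
    "contact",
    "act_exchange_info",
    "act_promote",
    "act_events",
    "act_develop_sustain",
    "act_share_resources",
    "ref_send",
    "ref_receive",
    "ref_neither",
)

GRAPH_FORMATS = ("graphml", "edgelist_csv", "navigator_json")


def _require_columns(df: pd.DataFrame, required: Sequence[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{what}: missing column(s) {', '.join(missing)}")


def read_roster(path: PathLike) -> list[Agency]:
    """Read and validate a roster CSV (agency_id,name,agency_type,area_id)."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    _require_columns(df, ROSTER_COLUMNS, f"roster {path}")
    allowed = {t.value for t in AgencyType}
    seen: set[str] = set()
    roster: list[Agency] = []
    for i, rec in enumerate(df.itertuples(index=False), start=2):  # 1-based + header
        aid = rec.agency_id.strip()
        if not aid:
            raise ValidationError(f"roster row {i}: empty agency_id")
        if aid in seen:
            raise ValidationError(f"roster row {i}: duplicate agency_id {aid!r}")
        seen.add(aid)
        atype = rec.agency_type.strip()
        if atype not in allowed:
            raise ValidationError(
                f"roster row {i}: unknown agency_type {atype!r}; allowed: "
                f"{', '.join(sorted(allowed))}"
            )
        roster.append(
            Agency(
                agency_id=aid,
                name=rec.name,
                agency_type=AgencyType(atype),
                area_id=rec.area_id.strip(),
            )
        )
    return roster


def write_roster(roster: Sequence[Agency], path: PathLike) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(ROSTER_COLUMNS)
        for a in roster:
            w.writerow([a.agency_id, a.name, a.agency_type.value, a.area_id])


def _parse_flag(value: str, row: int, field: str) -> bool:
    v = value.strip()
    if v in ("0", ""):
        return False
    if v == "1":
        return True
    raise ValidationError(
        f"responses row {row}: field {field!r} must be 0 or 1, got {value!r}"
    )


def read_responses(
    path: PathLike,
    roster: Sequence[Agency],
    strict: bool = True,
) -> list[DyadReport]:
    """Read and validate a long-format survey response CSV.

    Rows naming an off-roster reporter or partner are rejected in strict
    mode; in lenient mode they are dropped and the count is logged.
    Self-dyads and contradictory referral flags are always errors.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    _require_columns(df, RESPONSE_COLUMNS, f"responses {path}")
    on_roster = {a.agency_id for a in roster}
    reports: list[DyadReport] = []
    dropped = 0
    for i, rec in enumerate(df.itertuples(index=False), start=2):
        reporter = rec.reporter_agency_id.strip()
        partner = rec.partner_agency_id.strip()
        if reporter == partner:
            raise ValidationError(
                f"responses row {i}: self-dyad ({reporter!r} reporting about itself)"
            )
        if reporter not in on_roster or partner not in on_roster:
            off = reporter if reporter not in on_roster else partner
            if strict:
                raise ValidationError(
                    f"responses row {i}: agency {off!r} is not on the roster"
                )
            dropped += 1
            continue
        try:
            contact = ContactLevel.from_label(rec.contact)
        except ValueError as exc:
            raise ValidationError(f"responses row {i}: {exc}") from None
        activities = frozenset(
            act
            for act in ACTIVITIES
            if _parse_flag(getattr(rec, f"act_{act}"), i, f"act_{act}")
        )
        send = _parse_flag(rec.ref_send, i, "ref_send")
        receive = _parse_flag(rec.ref_receive, i, "ref_receive")
        neither = _parse_flag(rec.ref_neither, i, "ref_neither")
        if neither and (send or receive):
            raise ValidationError(
                f"responses row {i}: ref_neither=1 contradicts ref_send/ref_receive"
            )
        reports.append(
            DyadReport(
                respondent_id=rec.respondent_id.strip(),
                reporter_agency_id=reporter,
                partner_agency_id=partner,
                contact=contact,
                activities=activities,
                referral_send=send,
                referral_receive=receive,
                referral_neither=neither,
            )
        )
    if dropped:
        logger.warning("responses %s: dropped %d off-roster row(s)", path, dropped)
    return reports


def write_responses(reports: Sequence[DyadReport], path: PathLike) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(RESPONSE_COLUMNS)
        for r in reports:
            w.writerow(
                [
                    r.respondent_id,
                    r.reporter_agency_id,
                    r.partner_agency_id,
                    r.contact.label,
                    *(int(act in r.activities) for act in ACTIVITIES),
                    int(r.referral_send),
                    int(r.referral_receive),
                    int(r.referral_neither),
                ]
            )


# ---------------------------------------------------------------------------
# graph formats
# ---------------------------------------------------------------------------

_NODE_KEYS = ("name", "agency_type", "area_id")


def _write_graphml(graph: RelationGraph, path: PathLike) -> None:
    root = ET.Element("graphml", xmlns="http://graphml.graphdrawing.org/xmlns")
    keys = [
        ("d_rel", "graph", "relationship", "string"),
        ("d_thr", "graph", "contact_threshold", "string"),
        ("d_name", "node", "name", "string"),
        ("d_type", "node", "agency_type", "string"),
        ("d_area", "node", "area_id", "string"),
        ("d_lvl", "edge", "contact_level", "string"),
        ("d_bidir", "edge", "bidirectional", "boolean"),
    ]
    for kid, domain, name, atype in keys:
        ET.SubElement(
            root, "key", id=kid, **{"for": domain, "attr.name": name, "attr.type": atype}
        )
    g = ET.SubElement(
        root,
        "graph",
        id=graph.relationship,
        edgedefault="directed" if graph.directed else "undirected",
    )
    ET.SubElement(g, "data", key="d_rel").text = graph.relationship
    if graph.contact_threshold is not None:
        thr = graph.contact_threshold
        ET.SubElement(g, "data", key="d_thr").text = (
            thr.label if isinstance(thr, ContactLevel) else str(thr)
        )
    for node in graph.nodes:
        el = ET.SubElement(g, "node", id=node)
        meta = graph.node_meta.get(node, {})
        for kid, name in (("d_name", "name"), ("d_type", "agency_type"), ("d_area", "area_id")):
            if name in meta:
                ET.SubElement(el, "data", key=kid).text = str(meta[name])
    bidir = graph.bidirectional_pairs()
    for u, v in sorted(graph.edges):
        el = ET.SubElement(g, "edge", source=u, target=v)
        lvl = graph.edge_levels.get((u, v))
        if lvl is not None:
            ET.SubElement(el, "data", key="d_lvl").text = lvl.label
        if graph.directed:
            pair = (u, v) if u < v else (v, u)
            ET.SubElement(el, "data", key="d_bidir").text = (
                "true" if pair in bidir else "false"
            )
    ET.indent(root)
    ET.ElementTree(root).write(path, encoding="utf-8", xml_declaration=True)


def read_graphml(path: PathLike) -> RelationGraph:
    """Read back a GraphML file written by :func:`write_graph`."""
    ns = {"g": "http://graphml.graphdrawing.org/xmlns"}
    root = ET.parse(path).getroot()
    key_names = {
        k.get("id"): k.get("attr.name") for k in root.findall("g:key", ns)
    }
    g = root.find("g:graph", ns)
    if g is None:
        raise ValidationError(f"{path}: no <graph> element")
    directed = g.get("edgedefault") == "directed"

    def data_of(el: ET.Element) -> dict[str, str]:
        return {
            key_names.get(d.get("key"), d.get("key")): (d.text or "")
            for d in el.findall("g:data", ns)
        }

    gdata = data_of(g)
    relationship = gdata.get("relationship", g.get("id", "unknown"))
    threshold = (
        ContactLevel.from_label(gdata["contact_threshold"])
        if "contact_threshold" in gdata
        else None
    )
    nodes: list[str] = []
    node_meta: dict[str, dict[str, str]] = {}
    for el in g.findall("g:node", ns):
        nid = el.get("id")
        nodes.append(nid)
        meta = {k: v for k, v in data_of(el).items() if k in _NODE_KEYS}
        if meta:
            node_meta[nid] = meta
    edges: set[tuple[str, str]] = set()
    edge_levels: dict[tuple[str, str], ContactLevel] = {}
    for el in g.findall("g:edge", ns):
        u, v = el.get("source"), el.get("target")
        e = (u, v) if directed or u < v else (v, u)
        edges.add(e)
        d = data_of(el)
        if "contact_level" in d:
            edge_levels[e] = ContactLevel.from_label(d["contact_level"])
    return RelationGraph(
        relationship=relationship,
        directed=directed,
        nodes=tuple(nodes),
        edges=frozenset(edges),
        contact_threshold=threshold,
        edge_levels=edge_levels,
        node_meta=node_meta,
    )


def _write_edgelist_csv(graph: RelationGraph, path: PathLike) -> None:
    has_levels = bool(graph.edge_levels)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        header = ["source", "target", "relationship"]
        if has_levels:
            header.append("contact_level")
        w.writerow(header)
        for u, v in sorted(graph.edges):
            row = [u, v, graph.relationship]
            if has_levels:
                lvl = graph.edge_levels.get((u, v))
                row.append(lvl.label if lvl is not None else "")
            w.writerow(row)


def write_graph(
    graph: RelationGraph, path: PathLike, format: str, seed: int = 0
) -> None:
    """Write one layer as GraphML, edge-list CSV, or navigator JSON."""
    if format == "graphml":
        _write_graphml(graph, path)
    elif format == "edgelist_csv":
        _write_edgelist_csv(graph, path)
    elif format == "navigator_json":
        from .report import write_layer_json  # local import: report depends on netstats

        write_layer_json(graph, path, seed=seed)
    else:
        raise ValidationError(
            f"unknown graph format {format!r}; allowed: {', '.join(GRAPH_FORMATS)}"
        )
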