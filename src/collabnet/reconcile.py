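"""Reconcile raw multi-respondent dyad reports into agency-level network layers.

Aggregation to the agency level follows three rules: the highest contact
value across an agency's respondents is kept, any respondent flagging an
activity counts, and any respondent selecting a referral direction counts
("Neither" is overridden by any send/receive selection).

Contact is treated as a nondirected relationship and symmetrized
conservatively: when both agencies of a pair report contact at yearly or
more, the *lower* of the two values is used so the tie is never
overestimated; when only one side reports yearly or more, that side's value
stands in.  Activities are symmetrized by union (a tie exists if either or
both sides report it).  Referrals stay directed: an arc A→B exists if A
reported sending to B and/or B reported receiving from A; a bidirectional
relationship is simply the presence of both arcs.
"""

from __future__ import annotations

from collections import defaultdict
from typing import Iterable, Literal, Mapping, Optional, Sequence

from .types import (
    ACTIVITIES,
    Agency,
    AgencyDyad,
    ContactLevel,
    CONTACT_THRESHOLDS,
    DyadReport,
    RelationGraph,
    undirected_edge,
)

ContactFallback = Literal["reported", "completed"]

#: Layer keys produced by :func:`build_area_layers`, in presentation order.
LAYER_KEYS: tuple[str, ...] = (
    "contact_weekly",
    "contact_monthly",
    "contact_quarterly",
    "contact_yearly",
    *ACTIVITIES,
    "referral",
)


def aggregate_to_agency(reports: Sequence[DyadReport]) -> list[AgencyDyad]:
    """Collapse respondent-level reports into one record per unordered pair.

    Per directed reporter→partner slot: contact is the ordinal maximum over
    that agency's respondents, each activity is an OR, and referral
    send/receive are ORs with "Neither" ignored whenever any respondent
    selected a direction.  The result is invariant to respondent ordering
    and to duplicated rows.
    """
    # directed slot -> (max contact or None, activity union, send, receive)
    contact: dict[tuple[str, str], ContactLevel] = {}
    acts: dict[tuple[str, str], set[str]] = defaultdict(set)
    send: dict[tuple[str, str], bool] = defaultdict(bool)
    recv: dict[tuple[str, str], bool] = defaultdict(bool)
    slots: set[tuple[str, str]] = set()

    for rep in reports:
        slot = (rep.reporter_agency_id, rep.partner_agency_id)
        slots.add(slot)
        prev = contact.get(slot)
        if prev is None or rep.contact > prev:
            contact[slot] = rep.contact
        acts[slot] |= rep.activities
        send[slot] = send[slot] or rep.referral_send
        recv[slot] = recv[slot] or rep.referral_receive

    pairs = sorted({undirected_edge(a, b) for a, b in slots})
    dyads: list[AgencyDyad] = []
    for a, b in pairs:
        dyads.append(
            AgencyDyad(
                agency_a=a,
                agency_b=b,
                contact_a_about_b=contact.get((a, b)),
                contact_b_about_a=contact.get((b, a)),
                activities_a=frozenset(acts.get((a, b), ())),
                activities_b=frozenset(acts.get((b, a), ())),
                send_a_to_b=send.get((a, b), False),
                receive_a_from_b=recv.get((a, b), False),
                send_b_to_a=send.get((b, a), False),
                receive_b_from_a=recv.get((b, a), False),
            )
        )
    return dyads


def symmetrize_contact(
    dyads: Iterable[AgencyDyad],
    fallback: ContactFallback = "reported",
    completed_agencies: Optional[set[str]] = None,
) -> dict[tuple[str, str], ContactLevel]:
    """Symmetrized contact edges with per-edge level.

    ``fallback`` controls what counts as a side having "responded yearly or
    more":

    * ``"reported"`` (default): a side responded iff its aggregated contact
      value is at least yearly, whether silence comes from survey
      nonresponse or an explicit "none".
    * ``"completed"``: an agency that completed the survey
      (``completed_agencies``) is taken at its word — an explicit or implied
      "none" from a completed survey vetoes the edge via the minimum rule;
      the one-sided fallback applies only against unit nonresponse.
    """
    if fallback not in ("reported", "completed"):
        raise ValueError(f"unknown contact fallback {fallback!r}")
    if fallback == "completed" and completed_agencies is None:
        raise ValueError("'completed' fallback requires completed_agencies")

    edges: dict[tuple[str, str], ContactLevel] = {}
    for d in dyads:
        va = d.contact_a_about_b if d.contact_a_about_b is not None else ContactLevel.NONE
        vb = d.contact_b_about_a if d.contact_b_about_a is not None else ContactLevel.NONE
        if fallback == "reported":
            a_responded = va >= ContactLevel.YEARLY
            b_responded = vb >= ContactLevel.YEARLY
        else:
            a_responded = d.agency_a in completed_agencies  # type: ignore[operator]
            b_responded = d.agency_b in completed_agencies  # type: ignore[operator]
        if a_responded and b_responded:
            level = min(va, vb)
        elif a_responded:
            level = va
        elif b_responded:
            level = vb
        else:
            level = ContactLevel.NONE
        if level >= ContactLevel.YEARLY:
            edges[(d.agency_a, d.agency_b)] = level
    return edges


def contact_graph_at_level(
    edges: Mapping[tuple[str, str], ContactLevel],
    level: ContactLevel,
    nodes: Sequence[str],
    node_meta: Optional[Mapping[str, Mapping[str, str]]] = None,
) -> RelationGraph:
    """Contact layer thresholded at ``level`` ("at least *level*" contact)."""
    if not isinstance(level, ContactLevel) or level == ContactLevel.NONE:
        raise ValueError(f"invalid contact threshold {level!r}")
    kept = {e: lvl for e, lvl in edges.items() if lvl >= level}
    return RelationGraph(
        relationship="contact",
        directed=False,
        nodes=tuple(nodes),
        edges=frozenset(kept),
        contact_threshold=level,
        edge_levels=kept,
        node_meta=dict(node_meta or {}),
    )


def activity_graph(
    dyads: Iterable[AgencyDyad],
    activity: str,
    nodes: Sequence[str],
    node_meta: Optional[Mapping[str, Mapping[str, str]]] = None,
) -> RelationGraph:
    """Nondirected activity layer: edge iff either side reported the activity."""
    if activity not in ACTIVITIES:
        raise ValueError(
            f"unknown activity {activity!r}; allowed: {', '.join(ACTIVITIES)}"
        )
    edges = frozenset(
        (d.agency_a, d.agency_b)
        for d in dyads
        if activity in d.activities_a or activity in d.activities_b
    )
    return RelationGraph(
        relationship=activity,
        directed=False,
        nodes=tuple(nodes),
        edges=edges,
        node_meta=dict(node_meta or {}),
    )


def referral_graph(
    dyads: Iterable[AgencyDyad],
    nodes: Sequence[str],
    node_meta: Optional[Mapping[str, Mapping[str, str]]] = None,
) -> RelationGraph:
    """Directed referral layer.

    An arc A→B exists if A reported sending referrals to B and/or B reported
    receiving referrals from A.  Bidirectionality is the presence of both
    arcs — applying the same union rule in each direction reproduces the
    two-sided bidirection wording exactly (checked exhaustively in tests).
    """
    arcs: set[tuple[str, str]] = set()
    for d in dyads:
        if d.send_a_to_b or d.receive_b_from_a:
            arcs.add((d.agency_a, d.agency_b))
        if d.send_b_to_a or d.receive_a_from_b:
            arcs.add((d.agency_b, d.agency_a))
    return RelationGraph(
        relationship="referral",
        directed=True,
        nodes=tuple(nodes),
        edges=frozenset(arcs),
        node_meta=dict(node_meta or {}),
    )


def build_area_layers(
    reports: Sequence[DyadReport],
    agencies: Sequence[Agency],
    fallback: ContactFallback = "reported",
) -> dict[str, RelationGraph]:
    """All ten layers for one service area from its validated reports.

    Produces four contact-threshold graphs, five activity graphs, and the
    directed referral graph, each over the full area roster (agencies with
    no reports remain as isolates).
    """
    nodes = tuple(a.agency_id for a in agencies)
    meta = {
        a.agency_id: {
            "name": a.name,
            "agency_type": a.agency_type.value,
            "area_id": a.area_id,
        }
        for a in agencies
    }
    dyads = aggregate_to_agency(reports)
    completed = {r.reporter_agency_id for r in reports}
    edges = symmetrize_contact(dyads, fallback=fallback, completed_agencies=completed)

    layers: dict[str, RelationGraph] = {}
    for level in CONTACT_THRESHOLDS:
        layers[f"contact_{level.label}"] = contact_graph_at_level(
            edges, level, nodes, meta
        )
    for act in ACTIVITIES:
        layers[act] = activity_graph(dyads, act, nodes, meta)
    layers["referral"] = referral_graph(dyads, nodes, meta)
    return layers
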