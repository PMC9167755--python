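"""Core domain types shared across the pipeline.

The unit of observation is a *dyad report*: one survey respondent's answers
about their agency's relationship with one partner agency.  Reports are
aggregated to agency level, reconciled into per-pair records, and finally
materialized as network layers (one per relationship type, and one per
contact-frequency threshold).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Optional


class AgencyType(str, enum.Enum):
    """Closed vocabulary of agency types appearing on a service-area roster."""

    FQHC = "fqhc"
    LHD = "lhd"
    SCHOOL = "school"
    COMMUNITY_PARTNER = "community_partner"
    UNIVERSITY_EXTENSION = "university_extension"
    HEALTHCARE_FACILITY = "healthcare_facility"


class ContactLevel(enum.IntEnum):
    """Ordinal contact frequency: none < yearly < quarterly < monthly < weekly."""

    NONE = 0
    YEARLY = 1
    QUARTERLY = 2
    MONTHLY = 3
    WEEKLY = 4

    @property
    def label(self) -> str:
        return self.name.lower()

    @classmethod
    def from_label(cls, label: str) -> "ContactLevel":
        try:
            return cls[label.strip().upper()]
        except KeyError:
            allowed = ", ".join(l.label for l in cls)
            raise ValueError(
                f"unknown contact level {label!r}; allowed: {allowed}"
            ) from None


#: The five collaborative activity types asked about in the survey, ordered
#: from least to most time/resource intensive (the order they are reported in).
ACTIVITIES: tuple[str, ...] = (
    "exchange_info",
    "promote",
    "events",
    "develop_sustain",
    "share_resources",
)

#: Human-readable activity names used in rendered reports.
ACTIVITY_TITLES: Mapping[str, str] = {
    "exchange_info": "Exchanging general information",
    "promote": "Promoting ongoing services or programs",
    "events": "Annual/one-time events",
    "develop_sustain": "Developing & sustaining ongoing services or programs",
    "share_resources": "Developing & sharing resources",
}

#: Contact thresholds from most to least restrictive.
CONTACT_THRESHOLDS: tuple[ContactLevel, ...] = (
    ContactLevel.WEEKLY,
    ContactLevel.MONTHLY,
    ContactLevel.QUARTERLY,
    ContactLevel.YEARLY,
)


class ValidationError(ValueError):
    """Malformed input data; message names the offending row/field."""


class ConfigError(ValueError):
    """Invalid configuration; message names the offending field."""


class UndefinedStatisticError(ValueError):
    """A statistic whose denominator vanishes for this input (e.g. N < 3)."""


@dataclass(frozen=True)
class Agency:
    """One rostered agency — a node in every layer of its area's network."""

    agency_id: str
    name: str
    agency_type: AgencyType
    area_id: str


@dataclass(frozen=True)
class DyadReport:
    """One respondent's raw answers about one partner agency.

    ``activities`` holds the names (from :data:`ACTIVITIES`) the respondent
    flagged.  A report with ``contact == NONE`` is still a report: its
    activity and referral flags count.  Absence of a report means the
    respondent said nothing about that partner.
    """

    respondent_id: str
    reporter_agency_id: str
    partner_agency_id: str
    contact: ContactLevel
    activities: frozenset[str] = frozenset()
    referral_send: bool = False
    referral_receive: bool = False
    referral_neither: bool = False

    def __post_init__(self) -> None:
        if self.reporter_agency_id == self.partner_agency_id:
            raise ValidationError(
                f"self-dyad: respondent {self.respondent_id!r} reports about "
                f"their own agency {self.reporter_agency_id!r}"
            )
        unknown = self.activities - set(ACTIVITIES)
        if unknown:
            raise ValidationError(f"unknown activities {sorted(unknown)!r}")
        if self.referral_neither and (self.referral_send or self.referral_receive):
            raise ValidationError(
                "referral 'neither' flagged together with send/receive in one "
                f"report (respondent {self.respondent_id!r}, partner "
                f"{self.partner_agency_id!r})"
            )


@dataclass
class AgencyDyad:
    """Agency-level record for one unordered pair, after respondent aggregation.

    ``contact_a_about_b is None`` means agency A filed no report at all about
    B, which is distinct from an explicit ``ContactLevel.NONE`` answer.
    Referral flags are kept in both directions because referrals are directed.
    """

    agency_a: str
    agency_b: str
    contact_a_about_b: Optional[ContactLevel] = None
    contact_b_about_a: Optional[ContactLevel] = None
    activities_a: frozenset[str] = frozenset()
    activities_b: frozenset[str] = frozenset()
    send_a_to_b: bool = False
    receive_a_from_b: bool = False
    send_b_to_a: bool = False
    receive_b_from_a: bool = False

    def __post_init__(self) -> None:
        if self.agency_a >= self.agency_b:
            raise ValueError("AgencyDyad requires agency_a < agency_b")


@dataclass
class RelationGraph:
    """One network layer: a relationship label over a fixed area roster.

    Nondirected edges are stored as sorted 2-tuples, directed edges as
    (source, target).  The node set is always the full area roster, so
    isolates are first-class.  ``edge_levels`` carries the symmetrized
    contact level for contact layers.
    """

    relationship: str
    directed: bool
    nodes: tuple[str, ...]
    edges: frozenset[tuple[str, str]]
    contact_threshold: Optional[ContactLevel] = None
    edge_levels: Mapping[tuple[str, str], ContactLevel] = field(default_factory=dict)
    node_meta: Mapping[str, Mapping[str, str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        node_set = set(self.nodes)
        if len(node_set) != len(self.nodes):
            raise ValueError("duplicate node ids")
        for u, v in self.edges:
            if u == v:
                raise ValueError(f"self-loop on {u!r}")
            if u not in node_set or v not in node_set:
                raise ValueError(f"edge ({u!r}, {v!r}) references unknown node")
            if not self.directed and u > v:
                raise ValueError("nondirected edges must be stored sorted")

    # -- basic accessors -------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def has_edge(self, u: str, v: str) -> bool:
        if self.directed:
            return (u, v) in self.edges
        return (min(u, v), max(u, v)) in self.edges

    def neighbors(self, node: str) -> Iterator[str]:
        """Adjacent nodes; for directed graphs, union of in- and out-neighbors."""
        for u, v in self.edges:
            if u == node:
                yield v
            elif v == node:
                yield u

    def adjacency(self) -> dict[str, list[str]]:
        """Undirected adjacency lists (directed edges contribute both ways)."""
        adj: dict[str, list[str]] = {v: [] for v in self.nodes}
        for u, v in self.edges:
            adj[u].append(v)
            if not self.directed:
                adj[v].append(u)
        return adj

    def degree(self, node: str) -> int:
        if self.directed:
            raise ValueError("degree is defined for nondirected layers; "
                             "use in_degree/out_degree")
        return sum(1 for u, v in self.edges if node in (u, v))

    def in_degree(self, node: str) -> int:
        if not self.directed:
            raise ValueError("in_degree requires a directed layer")
        return sum(1 for _, v in self.edges if v == node)

    def out_degree(self, node: str) -> int:
        if not self.directed:
            raise ValueError("out_degree requires a directed layer")
        return sum(1 for u, _ in self.edges if u == node)

    def isolates(self) -> list[str]:
        touched = {n for e in self.edges for n in e}
        return [n for n in self.nodes if n not in touched]

    def bidirectional_pairs(self) -> frozenset[tuple[str, str]]:
        """Unordered pairs connected by arcs in both directions (referrals)."""
        if not self.directed:
            return frozenset()
        return frozenset(
            (u, v) for u, v in self.edges if u < v and (v, u) in self.edges
        )


def undirected_edge(u: str, v: str) -> tuple[str, str]:
    """Canonical storage form of a nondirected edge."""
    if u == v:
        raise ValueError(f"self-edge on {u!r}")
    return (u, v) if u < v else (v, u)
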