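"""Seeded synthetic rosters, planted multiplex networks, and noisy survey responses.

The generator emulates the study design the analysis pipeline assumes: a
handful of rural service areas of 24-45 agencies each, a nondirected contact
relationship at four ordinal frequencies, five nondirected collaborative
activity layers whose density declines with activity intensity, a directed
referral layer, and multi-respondent per-agency reporting with configurable
noise.  Planted "true" networks let every downstream stage be tested by
exact recovery.

Layer construction per area:

* contact: Erdős–Rényi draw with per-pair probability ``target/(n-1)``;
  each realized edge gets an ordinal level drawn from ``contact_level_mix``.
* activities: each activity samples its edges from the realized *contact*
  edge set, with inclusion probability ``target·n/2 / |E_contact|``.  This
  guarantees every activity tie is backed by contact and makes the expected
  average degree equal the target conditionally on the contact draw.
* referrals: independent directed Erdős–Rényi draw with per-arc probability
  ``target/(n-1)``, giving ``target`` expected arcs per agency.

All randomness descends from a single seed through per-(area, stage)
substreams, so adding areas never perturbs earlier areas.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np

from .types import (
    ACTIVITIES,
    Agency,
    AgencyType,
    ConfigError,
    ContactLevel,
    DyadReport,
    undirected_edge,
)

#: Relationship labels the generator plants, in generation order.
RELATIONSHIPS: tuple[str, ...] = ("contact", *ACTIVITIES, "referral")

_DEFAULT_TYPE_MIX: Mapping[AgencyType, float] = {
    AgencyType.FQHC: 0.05,
    AgencyType.LHD: 0.10,
    AgencyType.SCHOOL: 0.20,
    AgencyType.COMMUNITY_PARTNER: 0.40,
    AgencyType.UNIVERSITY_EXTENSION: 0.05,
    AgencyType.HEALTHCARE_FACILITY: 0.20,
}

# Published cross-area mean average degrees for the five activities; contact
# and referral targets are modeling choices (see docs/methods.md).
_DEFAULT_TARGETS: Mapping[str, float] = {
    "contact": 16.0,
    "exchange_info": 11.7,
    "promote": 8.4,
    "events": 6.6,
    "develop_sustain": 5.1,
    "share_resources": 4.8,
    "referral": 5.0,
}

_DEFAULT_LEVEL_MIX: Mapping[ContactLevel, float] = {
    ContactLevel.YEARLY: 0.2,
    ContactLevel.QUARTERLY: 0.3,
    ContactLevel.MONTHLY: 0.3,
    ContactLevel.WEEKLY: 0.2,
}


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-design parameters for the synthetic survey.

    Defaults reproduce the published study conditions: five service areas of
    24-45 agencies, activity average degrees between 4.8 and 11.7, and a
    modest rate of second respondents per agency.
    """

    n_areas: int = 5
    agencies_per_area: tuple[int, int] = (24, 45)
    type_mix: Mapping[AgencyType, float] = field(
        default_factory=lambda: dict(_DEFAULT_TYPE_MIX)
    )
    extra_respondent_prob: float = 0.15
    target_avg_degree: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_TARGETS)
    )
    contact_level_mix: Mapping[ContactLevel, float] = field(
        default_factory=lambda: dict(_DEFAULT_LEVEL_MIX)
    )
    report_prob: float = 0.9
    false_report_prob: float = 0.02
    contact_perturb_prob: float = 0.1
    seed: int = 0

    def validate(self) -> None:
        if self.n_areas < 1:
            raise ConfigError("n_areas must be >= 1")
        lo, hi = self.agencies_per_area
        if lo < 3:
            raise ConfigError("agencies_per_area.min must be >= 3")
        if hi < lo:
            raise ConfigError("agencies_per_area.max must be >= min")
        if abs(sum(self.type_mix.values()) - 1.0) > 1e-9:
            raise ConfigError("type_mix proportions must sum to 1")
        if any(p < 0 for p in self.type_mix.values()):
            raise ConfigError("type_mix proportions must be nonnegative")
        for name in ("extra_respondent_prob", "report_prob",
                     "false_report_prob", "contact_perturb_prob"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {p}")
        if abs(sum(self.contact_level_mix.values()) - 1.0) > 1e-9:
            raise ConfigError("contact_level_mix must sum to 1")
        if ContactLevel.NONE in self.contact_level_mix:
            raise ConfigError(
                "contact_level_mix is conditional on contact existing; "
                "'none' is not a valid key"
            )
        unknown = set(self.target_avg_degree) - set(RELATIONSHIPS)
        if unknown:
            raise ConfigError(
                f"target_avg_degree has unknown relationships {sorted(unknown)!r}"
            )
        contact_target = self.target_avg_degree.get("contact", 0.0)
        for rel, target in self.target_avg_degree.items():
            if target < 0:
                raise ConfigError(f"target_avg_degree[{rel!r}] must be >= 0")
            if target > lo - 1:
                raise ConfigError(
                    f"target_avg_degree[{rel!r}]={target} infeasible: exceeds "
                    f"min area size - 1 = {lo - 1}"
                )
            if rel in ACTIVITIES and target > contact_target:
                raise ConfigError(
                    f"target_avg_degree[{rel!r}]={target} exceeds the contact "
                    f"target {contact_target}; activity ties require contact"
                )


@dataclass
class AreaTruth:
    """Planted networks for one service area."""

    area_id: str
    agency_ids: tuple[str, ...]
    contact_edges: dict[tuple[str, str], ContactLevel]
    activity_edges: dict[str, frozenset[tuple[str, str]]]
    referral_arcs: frozenset[tuple[str, str]]


@dataclass
class TrueNetworkSet:
    """Planted truth for every area, keyed by area id."""

    areas: dict[str, AreaTruth]


def _rng(seed: int, area_index: int, stage: int) -> np.random.Generator:
    """Per-(area, stage) substream; stable as areas are added."""
    return np.random.default_rng(np.random.SeedSequence([seed, area_index, stage]))


def generate_roster(config: GeneratorConfig) -> list[Agency]:
    """Generate the agency roster for every area.

    Per-area agency counts are uniform over ``agencies_per_area``; types are
    drawn iid from ``type_mix``.  Ids are stable under the seed.
    """
    config.validate()
    lo, hi = config.agencies_per_area
    types = sorted(config.type_mix, key=lambda t: t.value)
    probs = np.array([config.type_mix[t] for t in types], dtype=float)
    probs = probs / probs.sum()
    roster: list[Agency] = []
    for i in range(config.n_areas):
        rng = _rng(config.seed, i, 0)
        area_id = f"area{i + 1}"
        n = int(rng.integers(lo, hi + 1))
        drawn = rng.choice(len(types), size=n, p=probs)
        for j in range(n):
            atype = types[int(drawn[j])]
            roster.append(
                Agency(
                    agency_id=f"{area_id}-A{j + 1:02d}",
                    name=f"{atype.value.replace('_', ' ').title()} {j + 1} ({area_id})",
                    agency_type=atype,
                    area_id=area_id,
                )
            )
    return roster


def _sample_pairs(
    rng: np.random.Generator, pairs: Sequence[tuple[str, str]], p: float
) -> list[tuple[str, str]]:
    if not pairs or p <= 0.0:
        rng.random(len(pairs))  # keep stream position stable across targets
        return []
    mask = rng.random(len(pairs)) < p
    return [pair for pair, hit in zip(pairs, mask) if hit]


def generate_true_networks(
    roster: Sequence[Agency], config: GeneratorConfig
) -> TrueNetworkSet:
    """Plant one contact, five activity, and one referral layer per area."""
    config.validate()
    if not roster:
        raise ConfigError("roster is empty")
    by_area: dict[str, list[Agency]] = {}
    for agency in roster:
        by_area.setdefault(agency.area_id, []).append(agency)

    levels = sorted(config.contact_level_mix, key=int)
    level_probs = np.array([config.contact_level_mix[l] for l in levels], dtype=float)
    level_probs = level_probs / level_probs.sum()

    areas: dict[str, AreaTruth] = {}
    for area_index, area_id in enumerate(by_area):
        ids = tuple(a.agency_id for a in by_area[area_id])
        n = len(ids)
        if n < 3:
            raise ConfigError(f"area {area_id!r} has fewer than 3 agencies")
        rng = _rng(config.seed, area_index, 1)
        pairs = [(ids[i], ids[j]) for i in range(n) for j in range(i + 1, n)]

        # contact layer with per-edge ordinal level
        t_contact = config.target_avg_degree.get("contact", 0.0)
        contact = _sample_pairs(rng, pairs, min(1.0, t_contact / (n - 1)))
        drawn = rng.choice(len(levels), size=len(contact), p=level_probs)
        contact_edges = {e: levels[int(k)] for e, k in zip(contact, drawn)}

        # activity layers: subsets of the contact edge set, calibrated so the
        # conditional expected average degree equals the target
        activity_edges: dict[str, frozenset[tuple[str, str]]] = {}
        for act in ACTIVITIES:
            target = config.target_avg_degree.get(act, 0.0)
            q = 0.0 if not contact else min(1.0, target * n / 2.0 / len(contact))
            activity_edges[act] = frozenset(_sample_pairs(rng, contact, q))

        # directed referral layer
        t_ref = config.target_avg_degree.get("referral", 0.0)
        ordered = [(u, v) for u in ids for v in ids if u != v]
        referral = frozenset(_sample_pairs(rng, ordered, min(1.0, t_ref / (n - 1))))

        areas[area_id] = AreaTruth(
            area_id=area_id,
            agency_ids=ids,
            contact_edges=contact_edges,
            activity_edges=activity_edges,
            referral_arcs=referral,
        )
    return TrueNetworkSet(areas=areas)


def _perturb_level(
    level: ContactLevel, rng: np.random.Generator, prob: float
) -> ContactLevel:
    """One ordinal step of reporting noise, never crossing into 'none'."""
    if rng.random() >= prob:
        return level
    if level == ContactLevel.YEARLY:
        step = 1
    elif level == ContactLevel.WEEKLY:
        step = -1
    else:
        step = 1 if rng.random() < 0.5 else -1
    return ContactLevel(int(level) + step)


class _RowBuilder:
    """Accumulates one respondent's flags about one partner into a report row."""

    __slots__ = ("contact", "activities", "send", "receive")

    def __init__(self) -> None:
        self.contact = ContactLevel.NONE
        self.activities: set[str] = set()
        self.send = False
        self.receive = False


def generate_survey_responses(
    truth: TrueNetworkSet,
    roster: Sequence[Agency],
    config: GeneratorConfig,
) -> list[DyadReport]:
    """Simulate noisy multi-respondent survey reports about the planted truth.

    Every agency gets one respondent, and a second with probability
    ``extra_respondent_prob``.  Each respondent independently reports each
    true tie incident to their agency with probability ``report_prob``
    (contact levels perturbed one ordinal step with probability
    ``contact_perturb_prob``), and fabricates a contact report about an
    unrelated rostered agency with probability ``false_report_prob``.
    Referrals are reported from each endpoint's own perspective: the sender
    side reports "send", the receiver side reports "receive".
    """
    config.validate()
    roster_ids = {a.agency_id for a in roster}
    reports: list[DyadReport] = []

    for area_index, area_id in enumerate(truth.areas):
        area = truth.areas[area_id]
        missing = set(area.agency_ids) - roster_ids
        if missing:
            raise ConfigError(
                f"truth for {area_id!r} references agencies not on the roster: "
                f"{sorted(missing)[:3]!r}..."
            )
        rng = _rng(config.seed, area_index, 2)
        ids = area.agency_ids

        # index true ties per agency
        contact_of: dict[str, dict[str, ContactLevel]] = {a: {} for a in ids}
        for (u, v), lvl in area.contact_edges.items():
            contact_of[u][v] = lvl
            contact_of[v][u] = lvl
        acts_of: dict[str, dict[str, set[str]]] = {a: {} for a in ids}
        for act, edges in area.activity_edges.items():
            for u, v in edges:
                acts_of[u].setdefault(v, set()).add(act)
                acts_of[v].setdefault(u, set()).add(act)
        sends_of: dict[str, set[str]] = {a: set() for a in ids}
        recvs_of: dict[str, set[str]] = {a: set() for a in ids}
        for u, v in sorted(area.referral_arcs):
            sends_of[u].add(v)
            recvs_of[v].add(u)

        for agency in ids:
            n_resp = 2 if rng.random() < config.extra_respondent_prob else 1
            related = sorted(
                set(contact_of[agency])
                | set(acts_of[agency])
                | sends_of[agency]
                | recvs_of[agency]
            )
            unrelated = [
                b for b in ids if b != agency and b not in related
            ]
            for r in range(1, n_resp + 1):
                rows: dict[str, _RowBuilder] = {}

                def row(partner: str) -> _RowBuilder:
                    if partner not in rows:
                        rows[partner] = _RowBuilder()
                    return rows[partner]

                for partner in related:
                    lvl = contact_of[agency].get(partner)
                    if lvl is not None and rng.random() < config.report_prob:
                        row(partner).contact = _perturb_level(
                            lvl, rng, config.contact_perturb_prob
                        )
                    for act in ACTIVITIES:
                        if act in acts_of[agency].get(partner, ()):
                            if rng.random() < config.report_prob:
                                row(partner).activities.add(act)
                    if partner in sends_of[agency]:
                        if rng.random() < config.report_prob:
                            row(partner).send = True
                    if partner in recvs_of[agency]:
                        if rng.random() < config.report_prob:
                            row(partner).receive = True

                if config.false_report_prob > 0.0:
                    hits = rng.random(len(unrelated)) < config.false_report_prob
                    for partner, hit in zip(unrelated, hits):
                        if hit:
                            k = int(rng.choice(4)) + 1
                            row(partner).contact = ContactLevel(k)

                respondent_id = f"{agency}-r{r}"
                for partner in sorted(rows):
                    b = rows[partner]
                    reports.append(
                        DyadReport(
                            respondent_id=respondent_id,
                            reporter_agency_id=agency,
                            partner_agency_id=partner,
                            contact=b.contact,
                            activities=frozenset(b.activities),
                            referral_send=b.send,
                            referral_receive=b.receive,
                            referral_neither=not (b.send or b.receive),
                        )
                    )
    return reports


def truth_layers(area: AreaTruth) -> dict:
    """Materialize an area's planted truth as the ten analysis layers.

    Uses the same layer constructors as the reconciliation path, so planted
    truth and recovered networks are directly comparable.
    """
    from .reconcile import contact_graph_at_level  # layer constructors live there
    from .types import CONTACT_THRESHOLDS, RelationGraph

    nodes = area.agency_ids
    layers: dict[str, RelationGraph] = {}
    for level in CONTACT_THRESHOLDS:
        layers[f"contact_{level.label}"] = contact_graph_at_level(
            area.contact_edges, level, nodes
        )
    for act in ACTIVITIES:
        layers[act] = RelationGraph(
            relationship=act,
            directed=False,
            nodes=nodes,
            edges=area.activity_edges[act],
        )
    layers["referral"] = RelationGraph(
        relationship="referral",
        directed=True,
        nodes=nodes,
        edges=area.referral_arcs,
    )
    return layers


def noiseless(config: GeneratorConfig) -> GeneratorConfig:
    """Copy of ``config`` with perfect single-respondent reporting."""
    return replace(
        config,
        report_prob=1.0,
        false_report_prob=0.0,
        contact_perturb_prob=0.0,
        extra_respondent_prob=0.0,
    )
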