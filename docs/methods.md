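# Methods

## The measurement problem

A roster-method network survey asks each respondent, for every other agency
on their service area's roster, about (a) contact frequency on an ordinal
scale none < yearly < quarterly < monthly < weekly, (b) collaboration on
five activity types, and (c) referrals sent and/or received. Three design
facts shape the analysis:

1. **Multiple respondents per agency.** The unit of analysis is the agency,
   so respondent answers must be aggregated within an agency first.
2. **Two reports per nondirected tie.** Contact and the activities are
   conceptually symmetric, but the two sides rarely answer identically.
3. **Directed referrals observed from both ends.** A referral flow A→B can
   be evidenced by A ("we send to B") or by B ("we receive from A").

## Reconciliation rules

Aggregation within an agency (per partner): ordinal **maximum** for
contact; **OR** for each activity flag; **OR** for referral send/receive,
with an explicit "Neither" ignored whenever any respondent selected a
direction. A row with contact "none" is still a report — its activity and
referral flags count — and is distinct from the absence of any row.

Symmetrization across the pair:

- **Contact** — if both sides report contact at yearly or more, the edge
  takes the *lower* of the two values (conservative: never overestimates);
  if exactly one side reports yearly or more, its value is used; otherwise
  no edge. The thresholded layers ("at least weekly", …, "at least
  yearly") are nested by construction.
- **Activities** — union: a tie exists if either or both sides reported it.
- **Referrals** — arc A→B iff A reported sending to B and/or B reported
  receiving from A; symmetrically for B→A. A bidirectional relationship is
  the presence of both arcs. Applying the union rule independently in each
  direction reproduces the usual two-sided bidirectionality wording
  ("both named each other, or one side reported both roles"); the test
  suite checks all 16 answer combinations against a hand-written case
  table.

**Ambiguity and the `contact_fallback` switch.** The one-sided contact
fallback can be read two ways when a pair's other agency *did* complete the
survey but reported no contact: either the reported value is what counts
(silence and "none" are equivalent — fallback applies) or a completed
survey's "none" is an explicit answer that vetoes the edge via the minimum
rule. The package defaults to the first reading (`reported`), which keys
only on reported values and makes the rule total; the second (`completed`)
is available via `--contact-fallback completed` for sensitivity analysis.

Reports naming off-roster partners are a hard error in strict mode and are
dropped with a logged count in lenient mode. Reports that cross service
areas are always dropped with a logged count: each area is analyzed as a
separate bounded network.

## Statistics

All statistics are computed from first principles on the package's own edge
sets; networkx appears only as an independent oracle in tests.

- **Degree / in-degree / out-degree** by direct counting. A mutual referral
  partner contributes once to in-degree and once to out-degree.
- **Betweenness** (nondirected layers): raw, unnormalized, over unordered
  pairs, with equal-length geodesics splitting credit equally and
  unreachable pairs contributing nothing. Implemented with Brandes'
  dependency accumulation (O(N·E)); the test suite proves exact agreement
  with explicit all-shortest-paths enumeration on every random graph up to
  8 nodes it draws, including disconnected ones.
- **Centralization**: C = Σᵢ(c_max − cᵢ) / T(N), where T(N) is the maximum
  of the numerator over all graphs with N nodes. T = (N−1)(N−2) for
  nondirected degree and (N−1)² for in- and out-degree (star maxima);
  T = (N−1)²(N−2)/2 for raw nondirected betweenness. For directed *total*
  degree, T = 2(N−1)(N−2), attained by the reciprocal star: with
  c_max = 2(N−1) the center needs all 2(N−1) arcs, each arc adds 2 to
  Σcᵢ, so Σᵢ(c_max − cᵢ) ≤ 2N(N−1) − 4(N−1) = 2(N−1)(N−2). The test
  suite verifies all four maxima by exhaustive enumeration of every graph
  on up to 5 nodes (up to 4 for the directed indices). Centralization is
  undefined for N < 3 (raises), and betweenness centralization is computed
  for nondirected layers only. Isolates stay in N, so disconnected layers
  are normalized over the full roster.
- **Average degree**: 2E/N for nondirected layers. For directed layers the
  convention is ambiguous in the field, so both are emitted, clearly
  labeled: `average_degree` = E/N (arcs per agency) and
  `total_degree_mean` = 2E/N.
- **Response rates**: 100·completed/invited, rounded half-up to one
  decimal (decimal arithmetic, not binary floats).
- **Cross-area summaries**: mean and sample SD (n−1 denominator — the areas
  are a sample of rural service areas) per statistic per layer; SD is
  flagged undefined with a single area. Rounding (1 decimal for average
  degree, 3 for centralizations) happens only at render time; computations
  keep full precision.

## Synthetic survey generator

The generator emulates the study design so the pipeline can be exercised
and calibrated without the restricted survey data. Defaults are the study
conditions: 5 service areas, 24–45 agencies each, agency types drawn from a
fixed mix dominated by community partners, and a 15% chance of a second
respondent per agency (the study had 182 respondents for 158 agencies).

Planted truth per area:

- **Contact**: Erdős–Rényi with edge probability `target/(n−1)`; each edge
  gets a level from `contact_level_mix` (default 0.2 / 0.3 / 0.3 / 0.2 for
  yearly / quarterly / monthly / weekly — contact is mostly routine, with
  weekly contact rarer).
- **Activities**: each activity's edges are a random subset of the realized
  contact edges, with inclusion probability `target·n/2 / |E_contact|`.
  This enforces "collaborators are in contact" and makes the expected
  average degree equal the target conditionally on the contact draw, so
  calibration error is pure Monte-Carlo noise. Activity targets default to
  the published cross-area means: 11.7 (exchanging information), 8.4
  (promoting), 6.6 (events), 5.1 (developing & sustaining), 4.8 (sharing
  resources). The contact target is not published; 16.0 was chosen once as
  a plausible value above the densest activity (it must dominate all
  activity targets for the subset construction to be feasible).
- **Referrals**: independent directed Erdős–Rényi with arc probability
  `target/(n−1)`, i.e. `target` expected arcs per agency; 5.0 by default
  (also unpublished — a modeling choice on the order of the sparser
  activities). Referral ties are not conditioned on contact.

Survey noise: each respondent independently reports each true tie incident
to their agency with probability `report_prob` (default 0.9); reported
contact levels take one ordinal step of noise with probability 0.1, never
crossing into "none" (so the minimum rule is exercised without destroying
ties); false-positive contact reports about unrelated agencies occur at
`false_report_prob` (default 0.02). Per-tie false-negative/false-positive
rates are not published for this kind of survey; these defaults are
modeling choices, not estimates. Referral arcs are reported from each
endpoint's own perspective (sender: "send"; receiver: "receive"), so the
union rule recovers an arc with probability 1 − (1 − p)² under one
respondent per side — a property the tests verify at p = 0.8.

Feasibility validation rejects any target above `min agencies − 1` and any
activity target above the contact target. A target exactly at n−1 is
allowed and yields the complete graph.

All randomness descends from one seed through `numpy` `SeedSequence`
substreams keyed by (seed, area index, stage), so identical seeds give
byte-identical outputs and adding an area never perturbs earlier areas.

**What the generator does not emulate.** Planted layers are density-
calibrated ER draws: no core–periphery structure, no assortativity by
agency type, no geographic clustering, and no systematic (non-random)
nonresponse. Passing recovery and calibration tests therefore demonstrates
that the reconciliation rules and statistics are implemented exactly, and
that the generator hits its density targets — not that real collaboration
networks look like ER graphs. Published centralization values depend on
degree *variance*, which ER draws do not reproduce, so only average degree
is used for calibration.

## Dissemination outputs

The navigator bundle is a self-contained JSON document per area (schema
shipped at `src/collabnet/schemas/navigator_bundle.schema.json`, version
1.0, validated with pydantic on read and write). Each of the ten layers
carries the node list with name/type, degree or in-/out-degree,
betweenness, deltas against the network average, and layout coordinates;
the edge list with contact level or bidirectionality flags; and the network
statistic table. Layout is Fruchterman–Reingold with a fixed iteration
count (60) and seeded initialization, so bundles are byte-identical under
the same seed. The bundle deliberately carries raw statistics and leaves
node-sizing transforms to the renderer. No web front end is included; the
bundle is the contract.

The static report is markdown: a five-activity summary table (mean ± SD of
average degree, degree centralization, betweenness centralization across
areas), top-k agencies per layer by degree and betweenness (ties at the
cut are all included), the isolate list, and the area's agency response
rate. Empty layers render "no connections reported".

## Problem sizes used in tests

The test suite and the acceptance script use 200 replicate areas of 30
agencies for calibration checks (standard error ≈ 0.03 links/agency on the
information-exchange layer), 20 seeds for exact round-trip recovery, and
exhaustive enumeration up to 5 nodes (undirected) / 4 nodes (directed) for
the centralization maxima — sizes at which the exhaustive oracles are exact
and the whole suite runs in well under a minute.

## Known limitations

- Tie strength is binary per layer; the number of confirming respondents is
  not used as an edge weight.
- Cross-sectional only: no longitudinal merging of survey waves.
- The contact fallback interpretation is a genuine ambiguity of the survey
  design; both readings are implemented, but results under the two can
  differ for pairs with asymmetric nonresponse.
- Directed betweenness and other centralities (closeness, eigenvector) are
  out of scope.
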