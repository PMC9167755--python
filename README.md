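# collabnet

Survey-to-network analysis of informal interorganizational collaboration.

Public-health and social-service agencies in a service area collaborate
without formal governance: they exchange information, co-host events,
develop and share resources, and cross-refer clients. A roster-method
network survey measures these relationships, but it produces messy raw
material — several respondents per agency, one-sided reports about a
two-sided tie, and directed referral answers given from each endpoint's
perspective. `collabnet` turns that raw material into analyzable multiplex
networks and practitioner-facing outputs:

- **Reconciliation** of respondent-level dyad reports into agency-level
  ties: within an agency the highest contact value wins, any activity
  participation counts, and any referral selection counts (an explicit
  "Neither" is overridden by any selection). Contact is symmetrized with
  the *minimum* of the two sides' values (falling back to the one
  responding side), so ties are never overestimated; activities are
  symmetrized by union; referrals stay directed, with an arc A→B if A
  reported sending to B and/or B reported receiving from A.
- **Layers**: contact at four thresholds (at least weekly / monthly /
  quarterly / yearly), five activity networks, and the directed referral
  network — all over the full area roster, so unconnected agencies remain
  visible as isolates.
- **Statistics**, computed from first principles (no graph-library calls in
  the analysis path): degree, in-/out-degree, raw shortest-path betweenness
  c_B(v) = Σ_{s<t} σ_st(v)/σ_st via Brandes' algorithm, average degree,
  and Freeman centralization C = Σ_i (c_max − c_i) / max Σ (c_max − c_i),
  with the star-graph maxima (N−1)(N−2) for nondirected degree, (N−1)² for
  in-/out-degree, 2(N−1)(N−2) for directed total degree, and
  (N−1)²(N−2)/2 for raw betweenness.
- **Summaries and dissemination**: cross-area mean ± sample SD per layer,
  node-vs-network-average deltas, a schema-validated per-area JSON bundle
  (statistics, edge lists, seeded force-directed layout coordinates) for
  interactive network-navigator front ends, and a static markdown
  infographic report.
- A **synthetic survey generator** with planted ground truth, calibrated to
  published cross-area average degrees (11.7 links/agency for information
  exchange down to 4.8 for resource sharing), so the whole pipeline is
  testable without access to restricted survey data.

## Worked example

```python
import collabnet as cn
from collabnet.pipeline import analyze_reports

cfg = cn.GeneratorConfig(seed=42)          # 5 areas of 24-45 agencies
roster = cn.generate_roster(cfg)
truth = cn.generate_true_networks(roster, cfg)
reports = cn.generate_survey_responses(truth, roster, cfg)
print(f"{len(roster)} agencies in {cfg.n_areas} areas; {len(reports)} dyad reports")

result = analyze_reports(roster, reports)
row = cn.network_summary(result.areas["area1"].layers["exchange_info"])
print(row.n_nodes, row.n_edges, round(row.average_degree, 1),
      round(row.degree_centralization, 3))
print(cn.response_rate(152, 182))
```

prints

```
164 agencies in 5 areas; 3602 dyad reports
25 153 12.2 0.17
83.5
```

Area 1's information-exchange network has 25 agencies and 153 reconciled
ties — each agency exchanges information with about 12 others, and a
degree centralization of 0.17 means connections are spread broadly rather
than concentrated on a hub. The last line is a survey response rate: 152
completed of 182 invited individuals is 83.5%. Across the five simulated
areas the information-exchange layer averages 11.9 ± 0.2 links per agency,
tracking the generator's calibration target of 11.7.

The same run from a shell:

```bash
collabnet simulate --seed 42 --out data/
collabnet analyze --roster data/roster.csv --responses data/responses.csv \
    --out results/ --seed 1
```

`results/` then holds per-area GraphML and edge-list files for all ten
layers, `node_stats.csv` / `network_stats.csv` / `summary.csv`, one
navigator bundle JSON per area (`bundles/`), and a markdown report per
area (`reports/`).

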