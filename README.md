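# discoursenet

Discourse network analysis of policy debates: from coded stakeholder
statements to actor congruence networks, advocacy-coalition detection,
coalition-level network measures, and temporal bipolarisation curves.

## The problem

Upstream public-health policies — sugar taxes, minimum alcohol pricing,
tobacco control — are contested in the media by coalitions of stakeholders:
health charities, campaign groups, advisory bodies and celebrity advocates
on one side; manufacturers, trade associations and free-market think tanks
on the other. Discourse network analysis turns coded media statements into
networks that make these advocacy coalitions, their cohesion, and their
polarisation over time measurable. `discoursenet` is for researchers who
have (or can code) a statement table — one row per attribution of agreement
or disagreement with a concept by an actor on a date — and want the full
network pipeline, plus a synthetic debate generator so every stage can be
tested without access to raw coded media data.

## The model

A *statement* attributes to actor *i* agreement (+1) or disagreement (−1)
with concept *c*. Statements are aggregated to stances: `sign(n_agree −
n_disagree)`, with exact ties *ambivalent*. For actors *i, j* let `c_ij`
be the number of concepts on which they hold the same non-ambivalent
stance, `d_ij` the number on which they oppose, and `|C_i|` the number of
distinct concepts actor *i* mentions. The tie weight is the **subtract
transformation with average activity normalisation**

    w_ij = (c_ij − d_ij) / ((|C_i| + |C_j|) / 2)  ∈ [−1, 1],

so only argumentative similarity in excess of disagreement counts, and how
*often* an actor is quoted does not. A threshold keeps `w_ij ≥ τ`
(default τ = 0.4, inclusive); everything else, including all conflictual
(negative) weights, becomes 0.

On the thresholded network:

* **coalitions** — Girvan–Newman edge-betweenness clustering (divisive
  removal of high-betweenness edges; dendrogram cut at maximum modularity,
  or at a requested cluster count);
* **measures** — size, density (ties over the theoretical maximum), Freeman
  degree centralisation `Σ_i(d_max − d_i)/((n−1)(n−2))`, and the external
  ratio (an actor's extra-coalition ties over all its ties, averaged over a
  coalition or a stakeholder type);
* **bipolarisation** — the maximum Newman–Girvan modularity
  `Q = Σ_c (e_cc − a_c²)` over an ensemble of eleven k = 2 clusterings
  (edge-betweenness, spectral, Kernighan–Lin, greedy-modularity,
  random-walk medoids, …). High values mean two segregated coalitions; many
  brokers pull it down. A sliding window (default 200 statements, step 1)
  traces bipolarisation over the debate, and a LOESS smoother exposes the
  trend.

## Worked example

```python
from discoursenet import (DebateConfig, generate_debate, build_network,
                          girvan_newman, summarise, polarisation_series,
                          loess_smooth)

cfg = DebateConfig(n_actors_per_coalition=(12, 12), n_intermediaries=2,
                   n_concepts=8, n_statements=800, p_on_message=0.9, seed=42)
debate, truth = generate_debate(cfg)

net = build_network(debate, tau=0.4)            # thresholded congruence network
coalitions = girvan_newman(net, stop=2)         # two-coalition accounting
print(summarise(net, coalitions).to_string(index=False))

series = loess_smooth(polarisation_series(debate, window=400, seed=42), span=0.3)
print(series.to_frame().iloc[[0, 200, 400]].to_string(index=False))
```

prints

```
       scope  size  centralisation_pct  density  external_ratio
full network    26                11.7     0.25             NaN
 coalition 0    13                26.5     0.53            0.05
 coalition 1    13                29.5     0.50            0.03
 window_index centre_date  bipolarisation  smoothed
            0  2015-09-22        0.472189  0.467556
          200  2016-02-17        0.472244  0.477150
          400  2016-07-17        0.488367  0.483891
```

The generator planted two 13-actor coalitions (12 partisans plus one
intermediary gravitating to each side); Girvan–Newman recovers both, each
internally dense (0.53 / 0.50 against 0.25 overall) and nearly closed to
the other side (external ratios 0.05 / 0.03). With 90% on-message stances
the debate is strongly polarised throughout: windowed bipolarisation stays
near its two-clique ceiling of 0.5.

The same pipeline runs from the shell:

```sh
discoursenet generate --actors 12 12 --statements 800 --seed 42 --out debate.csv
discoursenet run-all --statements debate.csv --window 400 --seed 42 --out results/
```

`run-all` writes, per period (full debate, before and after the configured
split date): the thresholded adjacency matrix (CSV), a GraphML export with
coalition attributes, the partition, the measures table, and the
bipolarisation series with its plot. Deposited adjacency matrices can be
analysed directly with `--matrix`, bypassing statement ingestion.

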