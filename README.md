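# crossfeed

Microbial populations in a shared, nutrient-limited batch culture rarely
stay metabolically uniform: cells secrete by-products of their growth, and
genetically different neighbors can re-consume them. `crossfeed` is a
toolkit for asking, from a stoichiometric metabolic model alone, *which*
gene-knockout strains differ enough in by-production to feed each other,
and *whether* a community of such strains actually outgrows the best of its
members. It is aimed at systems-biology practitioners working with
constraint-based models (SBML or BiGG-style JSON) who want to screen for
growth-efficient cross-feeding consortia before building them.

## What it computes

**Dynamic FBA for competing strains.** Time is split into quasi-steady
intervals `δt`; per interval and per strain an LP solves

    max μ   s.t.  S v = 0,  vmin ≤ v ≤ vmax,

followed by a parsimonious second stage minimizing Σ|v| at the growth
optimum. Biomass and medium then integrate exactly over the interval:

    b_i[t+δt]  = b_i[t] · e^{μ_i δt}
    exC[t+δt]  = exC[t] + Σ_i vex_i · b_i[t] · (e^{μ_i δt} − 1)/μ_i
    vmin_ex    = max(−exC/(δt·Σ_i b_i), −cap)     (same bound for every strain)

Each strain maximizes its own growth — there is no community objective —
and secreted metabolites become common goods the next interval.

**Diversity graphs.** Each viable strain's monoculture yields a blueprint
`Cmax(s)`, the peak concentration of every secreted by-product; strains are
connected with weight

    w_ij = max_s |Cmax_i(s) − Cmax_j(s)| / max(Cmax_i(s), Cmax_j(s)) ∈ [0,1],

which is independent of the initial source amount and can equivalently be
estimated from one flux-balance solution per strain (secretion per unit
source uptake). Thresholding at 0.6 gives a binary graph whose cliques are
candidate communities of pairwise-different strains; structurally identical
(redundant) strains compress onto supernodes, and exact clique search gives
the condition's diversity upper bound.

**Benefit.** A community's endpoint biomass `g` is compared with the
monoculture endpoints `m_i`: `benefit = (g − max m_i)/max m_i`, over the
members (relative) or every strain in the graph (absolute), with
cross-feeding interactions read from the exchange-flux time profiles and
composition-ratio scans for pairs.

## Worked example

The package ships two desk-scale fixture networks with analytically known
yields (see `docs/methods.md`). The overflow cross-feeder turns one unit of
glucose-like source into 0.05 gDW of biomass plus one unit of an excreted
by-product; deleting the by-product catabolism gene (`g_cb`) makes a pure
provider, deleting the main route (`g_cs`, with its half-strength variant
`g_ch`) makes a low-yield consumer that can live off the provider's leavings.

```
$ crossfeed make-fixtures demo
$ crossfeed benefit demo/crossfeed_toy.json demo/condition_crossfeed.yaml \
      --strains "provider=g_cb,consumer=g_cs+g_ch"
{
  "members": ["consumer", "provider"],
  "group_biomass": 0.8888942631348282,
  "relative_benefit": 0.7667555225770203,
  "interacting": true,
  "interactions": [
    {"metabolite": "byp_e", "producer": "provider", "consumer": "consumer"}
  ]
}
```

Alone, the provider ends at 0.503 gDW/L (= 0.003 + 0.05·10, substrate
exhaustion) and the consumer at 0.203; together they reach 0.889 gDW/L — a
relative benefit of +77% — because the by-product mass the provider cannot
use is routed through the consumer's catabolism. The interaction record
confirms the unidirectional `provider → consumer` exchange of `byp_e`.

The wild type, whose by-product re-uptake is capacity-limited, shows the
classic overflow two-phase profile (secrete fast, re-consume after the
source runs out):

```
$ crossfeed simulate-mono demo/crossfeed_toy.json demo/condition_crossfeed.yaml \
      --strain wild_type
wild_type: endpoint 1.00335 gDW/L after 14.0 h (stalled)
```

The full screen — knockout sweep, diversity graph, compression, cliques,
community benefits — runs as one pipeline:

```
$ crossfeed pipeline examples/pipeline_fixture.yaml
```

writing `sweep.tsv`, `graph.graphml`, `graph_stats.json`, `supernodes.tsv`,
`communities.tsv`, `benefits.tsv`, and a `manifest.json` recording every
threshold and the solver backend. On a genome-scale reconstruction the same
commands apply with the model path and a condition file giving the carbon
source, uptake caps, and in-excess metabolites
(`examples/condition_glucose.yaml` shows the standard batch settings:
0.003 gDW/L inoculum, 10 mmol/L source, δt = 0.1 h; the caps are
reconstruction-specific and must be supplied by the user).

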