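# Methods

## Batch monocultures: dynamic FBA

A batch culture is modeled as a sequence of quasi-steady states of length
`δt` (default 0.1 h). Within each interval the cell's flux distribution `v`
solves the linear program

```
maximize    μ                (biomass reaction flux, 1/h)
subject to  S v = 0          (intracellular steady state)
            vmin ≤ v ≤ vmax  (reversibility and capacity bounds)
```

followed by a second LP that minimizes the enzymatic cost `Σ|v|` while
holding the growth rate at its optimum (within a relative slack of 1e-9,
retried once at 1e-6). The second stage exists because the by-product
secretion fluxes read from `v` feed every downstream analysis, and the
growth optimum alone rarely pins them down. The absolute values are handled
through the forward/reverse variable split the solver interface already
maintains; the stored model is never rewritten. Flux minimization reduces
but does not eliminate degeneracy among equal-cost optima; remaining ties
are broken by the solver (GLPK by default, deterministic for fixed input),
which is why cross-implementation comparisons of flux profiles should use
tolerances.

Between solves, biomass grows exponentially and the medium integrates the
exponentially weighted exchange,

```
b[t+δt]   = b[t] · e^{μ δt}
exC[t+δt] = exC[t] + vex · b[t] · (e^{μ δt} − 1)/μ
```

with the closed-form limit `vex · b · δt` taken for μ < 1e-9/h (the printed
expression is 0/0 there, and a non-growing population can in principle
still exchange matter at steady state). Exchange fluxes are positive for
secretion and negative for uptake, a convention fixed across the package.

Substrate availability bounds the uptake per interval:

```
vmin_ex = max( −exC / (b_total · δt), −cap )
```

where `cap` is the per-substrate maximal uptake rate from the growth
condition (metabolites without a cap are limited by availability alone;
in-excess substrates such as oxygen and ammonia are bounded only by their
cap and never tracked). The bound is a linear budget while the within-step
growth is exponential, so a nearly empty pool can be overdrawn by at most
the factor `(e^{μδt}−1)/(μδt)`; overdrawn concentrations are clamped to
zero and the clamped mass is recorded on the trajectory (on the shipped
fixtures it stays below 0.1% of the initial carbon at δt = 0.1 h). We keep
the fixed-δt scheme rather than sub-stepping because the update rules above
are exact for constant μ and the endpoint error is first-order small:
halving δt moves fixture endpoints by well under 1%.

A simulation terminates when every strain's growth rate falls below
`μ_tol = 1e-6`/h ("stalled", usually nutrient depletion) or at
`max_time = 100` h. Both defaults are engineering choices exposed on the
growth condition and the simulation entry points.

## Co-cultures: independent competitors on a shared medium

A co-culture is the same scheme with one LP pair per strain per interval.
The strains are not given a collective objective: each maximizes its own
growth against the current medium. All strains see the same per-gDW uptake
bound computed from the *total* population biomass (the fairness assumption
of a well-mixed culture); there is no per-strain partitioning of the pool.
Secreted metabolites join the tracked medium at the concentration produced
and become consumable by every strain from the next interval on, which is
the mechanism that lets cross-feeding interactions develop. When the
population consists of identical cells the construction collapses exactly
to the monoculture dynamics — a property the test suite checks to 1e-9 per
time point.

## Diversity graphs

For each viable strain the monoculture yields a metabolic blueprint: the
maximum concentration `Cmax` each secreted by-product reaches over the run
(the primal carbon source and a configurable exclusion list — CO2, water,
protons, common inorganics — never count). Strain pairs are weighted by the
maximal relative blueprint difference,

```
w_ij = max_s |Cmax_i(s) − Cmax_j(s)| / max(Cmax_i(s), Cmax_j(s)) ∈ [0, 1],
```

with a by-product secreted by neither strain contributing 0 (the pair is
identical with respect to it). Weight 0 means identical by-production;
weight 1 means one strain secretes something the other does not.

Because every concentration in the dynamics scales linearly with the
initial source amount, the weights are independent of it, and the graph can
equally be estimated from a single flux-minimized FBA solution per strain
using by-production efficiencies (secretion flux over primal uptake flux)
in place of `Cmax` — the fast construction, one LP pair per strain instead
of a full batch run. One caveat of the discrete scheme: in the final,
partial interval of a phase the uptake bound is availability-limited while
capacity-limited side-processes (e.g. re-uptake of an overflow product)
are not, so for strains that simultaneously secrete and re-consume the
proportionality is exact only to ~1e-3 at δt = 0.1 h. Graphs whose weights
are {0, 1} are bit-identical across source amounts; intermediate weights
agree to that discretization error, and the dynamic and fast constructions
binarize identically on all shipped fixtures.

Node viability requires a positive initial growth rate (> μ_tol); the fast
construction additionally drops strains with no primal carbon uptake.

### Binary representation, compression, statistics

Cliques are sought in the binary graph obtained by keeping edges with
`w ≥ 0.6` (the threshold is inclusive; the fixtures' weight distributions
make the resulting graphs robust to the exact value). Structural
compression groups nodes with identical neighborhoods — metabolically
redundant strains — onto supernodes; since the graphs carry no self-loops,
equal neighborhoods imply mutual non-adjacency, the quotient adjacency is
all-or-none (verified by an expansion check), and a clique can take at most
one member per supernode.

Statistics follow the standard definitions and sit behind one formula layer
for easy replacement: strength centrality is the sum of incident weights
normalized by n−1; network centralization is the Freeman-style
`Σ(c_max − c_i)/(n−2)` over normalized strengths (1 for a binary star, 0
for regular graphs); clustering is the Watts–Strogatz local coefficient on
the binary graph (0 for degree < 2) with the network value its mean;
attribute assortativity is the Pearson correlation of a scalar node
attribute (e.g. a gene-conservation index) over edge endpoints counted in
both orientations, optionally using the edge weight as a multiplicity
weight — zero attribute variance raises a distinct error rather than
returning a number. Conservation density reports, per non-overlapping
window of 10 strains along an ordered list, the percentage whose attribute
exceeds 0.7 (trailing partial windows keep their actual size).

## Communities and growth benefit

Candidate communities are cliques (pairwise metabolically different
strains). The maximum clique size — the diversity upper bound of a
condition — is computed exactly by branch-and-bound; maximal cliques are
enumerated with pivoted Bron–Kerbosch. Both run on the compressed graph and
are decompressed to the lexicographically smallest representative per
supernode (recorded in the community's provenance; since supernode members
are by-production-identical the choice cannot affect a simulation), with an
option to expand all member combinations. Exactness is checked against an
independent bitmask subset-enumeration oracle on hundreds of seeded random
graphs.

Growth performance of a culture is its endpoint total biomass. A
community's benefit is

```
benefit = (g − max_i m_i) / max_i m_i
```

with `g` the co-culture endpoint and `m_i` monoculture endpoints under the
same total inoculum — over the members only (*relative*) or over every
strain of the graph (*absolute*). Endpoints reached by hitting `max_time`
rather than stalling are flagged non-comparable. Ratio scans rerun the
co-culture across initial composition fractions (default ninths, 1:9 …
9:1) at fixed total inoculum.

Cross-feeding links are read from the exchange-flux time profiles:
strain A feeds strain B through metabolite s when A sustains secretion
(flux > 1e-6 mmol/gDW/h for at least one interval, suppressing LP noise)
and B sustains uptake over a window that does not end before A's begins —
the pool mediates, so consumption may follow production (diauxic re-use
after source exhaustion) or overlap it. Pairs classify as bi-directional,
unidirectional, or none. The pair-mean predictor estimates a community's
performance as the mean of its constituent pairs' endpoints and flags
whether every pair interacts (the regime in which the prediction is
meaningful); a Pearson utility correlates predictions with simulations
over community batches.

## The fixture models

The test fixtures are deliberately small networks whose endpoints follow
from closed-form mass balances (`endpoint = b0 + yield × C0`), built so
single-gene deletions carve out the phenotypes the analyses target:

* **Overflow cross-feeder** (`make_crossfeed_model`): the main catabolic
  route obligatorily excretes one by-product unit per source unit
  (yield 0.05 gDW/mmol); re-uptake is capacity-limited (2 mmol/gDW/h), so
  the wild type secretes during fast growth and re-consumes afterwards — a
  diauxic two-phase profile. Deleting the by-product catabolism gene gives
  a pure provider; deleting the main route leaves a low-yield clean route
  (0.02) plus by-product catabolism — a consumer. A half-secretion route
  variant and a pair of never-used isozymes provide strains with
  intermediate (0.5) and zero weight against the provider.
* **Conversion chain** (`make_chain_model`): strain alpha's high-yield
  route (0.1) excretes M1; beta converts M1 to M2 for a marginal direct
  gain (0.005); gamma catabolizes M2 at high yield (0.2); everyone shares a
  clean baseline route (0.07). The yields satisfy the share condition under
  which diverting source to a slower partner costs more than any single
  conversion gains, so every pair is non-beneficial while the completed
  chain is — an indirect, group-level benefit that no pairwise analysis
  reveals.

Default batch settings across fixtures: 0.003 gDW/L inoculum, 10 mmol/L
single carbon source, δt = 0.1 h, uptake caps 10 mmol/gDW/h.

What the fixtures do **not** emulate: genome-scale redundancy (hundreds of
knockouts mapping onto a handful of secretion phenotypes), realistic
pathway topology and cofactor coupling, condition-dependent by-product
spectra, or biologically calibrated yields. Passing tests therefore
demonstrate the correctness of the machinery — dynamics, graph
construction, clique search, benefit accounting — and the reachability of
the qualitative phenomena (overflow diauxie, pure altruism, indirect
triplet benefit), not quantitative agreement with any organism. Analyses
of a genome-scale reconstruction run through exactly the same code paths
(`load_model` accepts SBML and BiGG-style JSON) but their numbers depend on
the reconstruction and the uptake caps supplied with the growth condition.

## Known limitations

* Alternate LP optima: even after flux minimization the secretion profile
  is not always unique; results are deterministic for a fixed solver but
  may shift across solver versions.
* The fixed-δt scheme overdraws nearly empty pools by a bounded, logged
  amount instead of sub-stepping; endpoint effects are < 1% at the default
  step and vanish as δt shrinks.
* Exchange capacity is the only uptake kinetics: no Michaelis–Menten
  saturation, no regulation (catabolite repression is mimicked in the
  fixtures by transporter capacity, not modeled).
* No death, lysis, fed-batch feeding, spatial structure, or stochastic
  population dynamics; evolutionary stability of communities (cheater
  invasion) is out of scope.
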