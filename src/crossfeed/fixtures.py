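"""Desk-scale stoichiometric models and graphs with known analytic behavior.

These generators stand in for a genome-scale network at test scale.  They are
first-class, deterministic model builders: every yield is chosen so the
endpoint biomass of a batch culture follows from a closed-form mass balance
(endpoint = b0 + yield * initial source), and GPR gating is arranged so that
single-gene deletions carve out the phenotypes studied throughout the
package:

* a *provider* that obligatorily secretes a by-product it cannot re-consume,
* a *consumer* that grows poorly on the main source but can catabolize the
  by-product,
* a wild type with overflow metabolism: its by-product re-uptake is
  capacity-limited, so it secretes during fast growth on the main source and
  re-consumes the accumulated pool afterwards (a diauxic two-phase profile),
* a three-strain conversion chain in which no pair is beneficial but the
  full triplet is (an indirect cross-feeding benefit).

Flux units are mmol/gDW/h, biomass yields gDW/mmol; the biomass reaction
consumes one unit of the precursor per unit growth rate, so a catabolic
reaction written ``source -> y * precursor`` grows at ``mu = y * uptake``.
"""

from __future__ import annotations

from dataclasses import dataclass

import cobra
import networkx as nx
import numpy as np

from .errors import ConditionError
from .fba_core import maximize_growth
from .model_io import GrowthCondition, StrainSpec

__all__ = [
    "CrossfeedSpec",
    "ChainSpec",
    "make_crossfeed_model",
    "crossfeed_condition",
    "crossfeed_strains",
    "make_chain_model",
    "chain_condition",
    "chain_strains",
    "make_linear_model",
    "make_two_route_model",
    "make_random_graph",
    "make_figure1_graph",
]

_UB = 1000.0


def _reaction(model, rid, stoich, lb=0.0, ub=_UB, gpr=""):
    rxn = cobra.Reaction(rid, lower_bound=lb, upper_bound=ub)
    model.add_reactions([rxn])
    rxn.add_metabolites({model.metabolites.get_by_id(m): c for m, c in stoich.items()})
    if gpr:
        rxn.gene_reaction_rule = gpr
    return rxn


def _metabolites(model, ids):
    model.add_metabolites(
        [cobra.Metabolite(mid, compartment=mid.rsplit("_", 1)[-1]) for mid in ids]
    )


# --------------------------------------------------------------------------- #
# overflow / cross-feeding model
# --------------------------------------------------------------------------- #

@dataclass(frozen=True)
class CrossfeedSpec:
    """Parameters of the overflow cross-feeding toy network.

    The main catabolic route converts one mmol of source into
    ``source_yield`` biomass plus ``byproduct_per_source`` mmol of an
    obligatorily excreted by-product.  A half-strength variant and a clean
    low-yield alternative route exist so that gene deletions produce strains
    with distinct secretion phenotypes.  Re-uptake of the by-product is
    limited to ``reuse_cap`` (overflow metabolism).
    """

    source_yield: float = 0.05          # gDW/mmol via the main route
    byproduct_per_source: float = 1.0   # mmol by-product per mmol source
    half_yield: float = 0.04            # main-route variant, half secretion
    half_byproduct: float = 0.5
    alt_yield: float = 0.02             # clean alternative route
    byproduct_yield: float = 0.05       # gDW/mmol when catabolizing by-product
    reuse_cap: float = 2.0              # mmol/gDW/h through the re-uptake step
    source_cap: float = 10.0            # exchange-level uptake caps
    byproduct_cap: float = 10.0

    def __post_init__(self):
        if min(self.source_yield, self.half_yield, self.alt_yield,
               self.byproduct_yield) <= 0:
            raise ConditionError("all yields must be positive")
        if self.byproduct_per_source <= 0:
            raise ConditionError("by-product stoichiometry must be positive")


def make_crossfeed_model(spec: CrossfeedSpec | None = None) -> cobra.Model:
    """Build the overflow cross-feeding network.

    Gene gating:

    ========  =======================================  =====================
    gene      reaction                                  deleting it yields
    ========  =======================================  =====================
    g_ts      source transport                         inviable strain
    g_cs      main catabolism (secretes by-product)    consumer (with g_ch)
    g_ch      half-secretion catabolic variant
    g_as1/2   alternative clean route (isozymes)       nothing alone
    g_ub      by-product re-uptake                     provider variant
    g_cb      by-product catabolism                    provider
    ========  =======================================  =====================
    """
    spec = spec or CrossfeedSpec()
    model = cobra.Model("crossfeed_toy")
    _metabolites(model, ["glc_e", "byp_e", "glc_c", "byp_c", "pre_c"])

    _reaction(model, "EX_glc_e", {"glc_e": -1})
    _reaction(model, "EX_byp_e", {"byp_e": -1})
    _reaction(model, "T_glc", {"glc_e": -1, "glc_c": 1}, gpr="g_ts")
    _reaction(
        model, "CAT_S",
        {"glc_c": -1, "pre_c": spec.source_yield, "byp_e": spec.byproduct_per_source},
        gpr="g_cs",
    )
    _reaction(
        model, "CAT_H",
        {"glc_c": -1, "pre_c": spec.half_yield, "byp_e": spec.half_byproduct},
        gpr="g_ch",
    )
    _reaction(model, "ALT_S", {"glc_c": -1, "pre_c": spec.alt_yield},
              gpr="g_as1 or g_as2")
    _reaction(model, "UPT_B", {"byp_e": -1, "byp_c": 1}, ub=spec.reuse_cap,
              gpr="g_ub")
    _reaction(model, "CAT_B", {"byp_c": -1, "pre_c": spec.byproduct_yield},
              gpr="g_cb")
    biomass = _reaction(model, "BIOMASS", {"pre_c": -1})
    model.objective = biomass.id

    if maximize_growth(model, {"EX_glc_e": -spec.source_cap}).mu <= 0:
        raise ConditionError("cross-feed spec leaves the wild type inviable")
    return model


def crossfeed_condition(initial_concentration: float = 10.0,
                        spec: CrossfeedSpec | None = None,
                        **overrides) -> GrowthCondition:
    """Batch condition on the toy glucose analogue (10 mmol/L, 0.003 gDW/L,
    dt = 0.1 h unless overridden)."""
    spec = spec or CrossfeedSpec()
    defaults = dict(
        carbon_source="glc_e",
        initial_concentration=initial_concentration,
        uptake_caps={"glc_e": spec.source_cap, "byp_e": spec.byproduct_cap},
        condition_id=f"glc@{initial_concentration:g}",
    )
    defaults.update(overrides)
    return GrowthCondition(**defaults)


def crossfeed_strains() -> dict[str, StrainSpec]:
    """The standard deletion strains of the cross-feeding model."""
    specs = [
        StrainSpec("wild_type"),
        StrainSpec("provider", frozenset({"g_cb"})),
        StrainSpec("provider_dup", frozenset({"g_cb", "g_as1"})),
        StrainSpec("half_provider", frozenset({"g_cs", "g_cb"})),
        StrainSpec("consumer", frozenset({"g_cs", "g_ch"})),
        StrainSpec("no_uptake", frozenset({"g_ts"})),
    ]
    return {s.strain_id: s for s in specs}


# --------------------------------------------------------------------------- #
# three-strain conversion chain (indirect benefit)
# --------------------------------------------------------------------------- #

@dataclass(frozen=True)
class ChainSpec:
    """Parameters of the three-strain conversion chain.

    Strain alpha runs a high-yield route that obligatorily excretes M1;
    strain beta converts M1 to M2 for a small direct gain; strain gamma
    catabolizes M2 at high yield.  All strains share a clean baseline route
    on the main source.  The yields are set so that diverting source to the
    slower-growing partners costs more than any single conversion step gains
    (every pair is non-beneficial), while the completed chain is.
    """

    path_a_yield: float = 0.1     # alpha's route, secretes M1
    m1_per_source: float = 1.0
    base_yield: float = 0.07      # clean baseline route on the source
    conversion_yield: float = 0.005   # beta's gain per mmol M1 converted
    m2_per_m1: float = 1.0
    m2_yield: float = 0.2         # gamma's gain per mmol M2
    uptake_cap: float = 10.0


def make_chain_model(spec: ChainSpec | None = None) -> cobra.Model:
    spec = spec or ChainSpec()
    model = cobra.Model("chain_toy")
    _metabolites(model, ["s_e", "m1_e", "m2_e", "s_c", "m1_c", "m2_c", "pre_c"])

    _reaction(model, "EX_s_e", {"s_e": -1})
    _reaction(model, "EX_m1_e", {"m1_e": -1})
    _reaction(model, "EX_m2_e", {"m2_e": -1})
    _reaction(model, "T_s", {"s_e": -1, "s_c": 1})
    _reaction(
        model, "PATH_A",
        {"s_c": -1, "pre_c": spec.path_a_yield, "m1_e": spec.m1_per_source},
        gpr="gA",
    )
    _reaction(model, "PATH_0", {"s_c": -1, "pre_c": spec.base_yield}, gpr="g0")
    _reaction(model, "UPT_M1", {"m1_e": -1, "m1_c": 1})
    _reaction(
        model, "CONV_B",
        {"m1_c": -1, "pre_c": spec.conversion_yield, "m2_e": spec.m2_per_m1},
        gpr="gB",
    )
    _reaction(model, "UPT_M2", {"m2_e": -1, "m2_c": 1})
    _reaction(model, "CAT_C", {"m2_c": -1, "pre_c": spec.m2_yield}, gpr="gC")
    biomass = _reaction(model, "BIOMASS", {"pre_c": -1})
    model.objective = biomass.id
    return model


def chain_condition(initial_concentration: float = 10.0,
                    spec: ChainSpec | None = None,
                    **overrides) -> GrowthCondition:
    spec = spec or ChainSpec()
    cap = spec.uptake_cap
    defaults = dict(
        carbon_source="s_e",
        initial_concentration=initial_concentration,
        uptake_caps={"s_e": cap, "m1_e": cap, "m2_e": cap},
        condition_id=f"s@{initial_concentration:g}",
    )
    defaults.update(overrides)
    return GrowthCondition(**defaults)


def chain_strains() -> dict[str, StrainSpec]:
    specs = [
        StrainSpec("alpha", frozenset({"gB", "gC"})),
        StrainSpec("beta", frozenset({"gA", "gC"})),
        StrainSpec("gamma", frozenset({"gA", "gB"})),
    ]
    return {s.strain_id: s for s in specs}


# --------------------------------------------------------------------------- #
# minimal LP fixtures
# --------------------------------------------------------------------------- #

def make_linear_model(yield_: float = 0.05, model_id: str = "linear_toy") -> cobra.Model:
    """Source -> biomass chain with growth rate exactly yield * uptake."""
    model = cobra.Model(model_id)
    _metabolites(model, ["s_e", "s_c", "pre_c"])
    _reaction(model, "EX_s_e", {"s_e": -1})
    _reaction(model, "T_s", {"s_e": -1, "s_c": 1})
    _reaction(model, "CAT", {"s_c": -1, "pre_c": yield_}, gpr="g_cat")
    biomass = _reaction(model, "BIOMASS", {"pre_c": -1})
    model.objective = biomass.id
    return model


def make_two_route_model(yield_: float = 0.1) -> cobra.Model:
    """Two equal-yield routes to biomass: one direct reaction vs a three-step
    detour.  Flux minimization must route everything through the short one."""
    model = cobra.Model("two_route_toy")
    _metabolites(model, ["s_e", "s_c", "x_c", "y_c", "pre_c"])
    _reaction(model, "EX_s_e", {"s_e": -1})
    _reaction(model, "T_s", {"s_e": -1, "s_c": 1})
    _reaction(model, "SHORT", {"s_c": -1, "pre_c": yield_})
    _reaction(model, "LONG1", {"s_c": -1, "x_c": 1})
    _reaction(model, "LONG2", {"x_c": -1, "y_c": 1})
    _reaction(model, "LONG3", {"y_c": -1, "pre_c": yield_})
    biomass = _reaction(model, "BIOMASS", {"pre_c": -1})
    model.objective = biomass.id
    return model


# --------------------------------------------------------------------------- #
# graph fixtures
# --------------------------------------------------------------------------- #

def make_random_graph(
    n: int,
    edge_prob: float,
    planted_clique_size: int = 0,
    seed: int = 0,
) -> nx.Graph:
    """Seeded Erdos-Renyi graph with an optional planted clique."""
    if planted_clique_size > n:
        raise ConditionError("planted clique cannot exceed the node count")
    graph = nx.gnp_random_graph(n, edge_prob, seed=seed)
    if planted_clique_size >= 2:
        rng = np.random.default_rng(seed)
        members = rng.choice(n, size=planted_clique_size, replace=False)
        for i, u in enumerate(members):
            for v in members[i + 1:]:
                graph.add_edge(int(u), int(v))
    return graph


def make_figure1_graph() -> nx.Graph:
    """The four-strain worked example: u connects to v, k and m, and k-m are
    adjacent, but v and k are metabolically similar (non-adjacent), so the
    largest community is {u, k, m}."""
    graph = nx.Graph()
    graph.add_edges_from(
        [("v", "u"), ("u", "k"), ("u", "m"), ("k", "m")], weight=1.0
    )
    return graph
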