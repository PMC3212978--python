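"""Diversity graphs: pairwise by-production differences between strains.

A strain's metabolic blueprint under a growth condition is the vector of
maximum concentrations each secreted by-product reaches during its
monoculture, ``Cmax_i(s) = max_t C_i(s, t)``.  The diversity graph connects
every pair of viable strains with the maximal relative difference of their
blueprints over all by-products,

    w_ij = max_s |Cmax_i(s) - Cmax_j(s)| / max(Cmax_i(s), Cmax_j(s)),

so that w = 0 marks strains identical in by-production and w = 1 marks a
by-product novel to one of the two.  A by-product secreted by neither strain
contributes 0 (the pair is identical with respect to it).

Because every concentration scales linearly with the initial amount of the
primal source, the weights are independent of that amount, and the same
graph can be estimated from a single flux-balance solution per strain using
by-production efficiencies (secretion flux over primal-source uptake flux)
in place of the concentration maxima — the fast construction.

The module also provides the binary representation (weight threshold,
default 0.6), structural compression of metabolically redundant nodes onto
supernodes, and the graph statistics used to characterize metabolic
diversity (strength centrality, network centralization, clustering,
attribute assortativity, and conservation density along an ordered strain
list).
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import cobra
import networkx as nx
import numpy as np
import pandas as pd

from .batch_dynamics import (
    FLUX_EPS,
    MU_TOL,
    UNBOUNDED_UPTAKE,
    BatchTrajectory,
)
from .errors import DomainError, UndefinedStatisticError
from .fba_core import solve_growth
from .model_io import GrowthCondition, StrainSpec, list_exchanges

__all__ = [
    "ByproductProfile",
    "CompressedGraph",
    "byproduct_profile",
    "edge_weight",
    "build_graph",
    "fast_graph_from_fba",
    "binarize",
    "compress",
    "strength_centrality",
    "network_centralization",
    "clustering_coefficient",
    "attribute_assortativity",
    "conservation_density",
    "write_edge_list",
]

#: external metabolites never counted as by-products (non-carbon or ubiquitous)
DEFAULT_EXCLUDED = frozenset({"co2_e", "h2o_e", "h_e", "o2_e", "nh4_e", "pi_e"})


@dataclass(frozen=True)
class ByproductProfile:
    """Per-strain map of by-product -> maximum secreted concentration
    (mmol/L), the strain's metabolic blueprint.  The primal carbon source is
    never part of the map."""

    strain_id: str
    cmax: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if any(v < 0 for v in self.cmax.values()):
            raise DomainError("Cmax values must be non-negative")


def byproduct_profile(
    traj: BatchTrajectory,
    strain_id: str | None = None,
    exclude: frozenset[str] = DEFAULT_EXCLUDED,
) -> ByproductProfile:
    """Extract the by-production blueprint from a monoculture trajectory.

    Raises :class:`DomainError` on a co-culture trajectory: blueprints are
    monoculture properties by definition.
    """
    if traj.n_strains != 1:
        raise DomainError(
            "by-product profiles are monoculture blueprints; got a "
            f"{traj.n_strains}-strain trajectory"
        )
    sid = strain_id or traj.strain_ids[0]
    primal = traj.condition.carbon_source
    cmax: dict[str, float] = {}
    for snapshot in traj.medium_series:
        for met, conc in snapshot.items():
            if met == primal or met in exclude:
                continue
            if conc > cmax.get(met, 0.0):
                cmax[met] = conc
    return ByproductProfile(sid, {m: c for m, c in cmax.items() if c > 0.0})


def edge_weight(p: ByproductProfile, q: ByproductProfile) -> float:
    """Maximal relative by-production difference between two strains, in
    [0, 1].  Pairs sharing no by-product universe get weight 0."""
    weight = 0.0
    for met in set(p.cmax) | set(q.cmax):
        a = p.cmax.get(met, 0.0)
        b = q.cmax.get(met, 0.0)
        top = max(a, b)
        if top > 0.0:
            weight = max(weight, abs(a - b) / top)
    return weight


def build_graph(
    profiles: Sequence[ByproductProfile],
    viability: Mapping[str, bool] | None = None,
    attributes: Mapping[str, float] | None = None,
    condition_id: str = "",
) -> nx.Graph:
    """Complete weighted diversity graph over the viable strains.

    Node attribute ``attr`` carries the optional per-strain scalar (e.g. a
    gene-conservation index); edge attribute ``weight`` is the diversity
    weight.  Fewer than two viable strains is a domain error.
    """
    viable = [
        p for p in profiles
        if viability is None or viability.get(p.strain_id, True)
    ]
    if len(viable) < 2:
        raise DomainError(
            f"a diversity graph needs at least 2 viable strains, got {len(viable)}"
        )
    graph = nx.Graph(condition_id=condition_id)
    for p in viable:
        graph.add_node(p.strain_id)
        if attributes and p.strain_id in attributes:
            graph.nodes[p.strain_id]["attr"] = float(attributes[p.strain_id])
    for i, p in enumerate(viable):
        for q in viable[i + 1:]:
            graph.add_edge(p.strain_id, q.strain_id, weight=edge_weight(p, q))
    return graph


def fast_graph_from_fba(
    strains: Sequence[tuple[StrainSpec, cobra.Model]],
    condition: GrowthCondition,
    attributes: Mapping[str, float] | None = None,
    exclude: frozenset[str] = DEFAULT_EXCLUDED,
    mu_tol: float = MU_TOL,
) -> nx.Graph:
    """Estimate the diversity graph from one flux-minimized FBA solution per
    strain, replacing concentration maxima by by-production efficiencies
    (secretion flux / primal uptake flux).  Strains that cannot grow or take
    up no primal carbon are excluded as inviable."""
    profiles: list[ByproductProfile] = []
    b0 = condition.initial_biomass
    for spec, model in strains:
        exchange_map = list_exchanges(model)
        bounds: dict[str, float] = {}
        for rxn, met in exchange_map.items():
            if met == condition.carbon_source:
                availability = condition.initial_concentration / (
                    b0 * condition.time_step
                )
                cap = condition.uptake_caps.get(met, availability)
                bounds[rxn] = -min(cap, availability)
            elif met in condition.in_excess:
                bounds[rxn] = -condition.uptake_caps.get(met, UNBOUNDED_UPTAKE)
            else:
                bounds[rxn] = 0.0
        sol = solve_growth(model, bounds)
        if not sol.optimal or sol.mu < mu_tol:
            continue
        primal_rxn = next(
            r for r, met in exchange_map.items()
            if met == condition.carbon_source
        )
        uptake = -float(sol.fluxes[primal_rxn])
        if uptake < FLUX_EPS:
            continue
        efficiency = {
            met: float(sol.fluxes[rxn]) / uptake
            for rxn, met in exchange_map.items()
            if met != condition.carbon_source
            and met not in exclude
            and float(sol.fluxes[rxn]) > FLUX_EPS
        }
        profiles.append(ByproductProfile(spec.strain_id, efficiency))
    return build_graph(
        profiles, attributes=attributes, condition_id=condition.condition_id
    )


# --------------------------------------------------------------------------- #
# binary representation and compression
# --------------------------------------------------------------------------- #

def binarize(graph: nx.Graph, threshold: float = 0.6) -> nx.Graph:
    """Keep edges with weight >= threshold (inclusive at the boundary)."""
    if not 0.0 < threshold <= 1.0:
        raise DomainError("threshold must lie in (0, 1]")
    binary = nx.Graph(**graph.graph)
    binary.add_nodes_from(graph.nodes(data=True))
    for u, v, data in graph.edges(data=True):
        if data.get("weight", 0.0) >= threshold:
            binary.add_edge(u, v, weight=data.get("weight", 0.0))
    return binary


@dataclass
class CompressedGraph:
    """Structural compression of a binary diversity graph.

    Metabolically redundant nodes — mutually non-adjacent nodes with exactly
    the same neighborhood — are merged onto supernodes; the quotient graph
    records the (all-or-none) adjacency between the classes.
    """

    supernodes: tuple[tuple, ...]
    membership: dict
    quotient: nx.Graph

    def representative(self, index: int):
        """Deterministic representative: lexicographically smallest member."""
        return self.supernodes[index][0]

    def sizes(self) -> list[int]:
        return [len(s) for s in self.supernodes]

    def verify(self, binary_graph: nx.Graph) -> None:
        """Check that expanding every quotient edge reproduces exactly the
        original edges between the two classes (all-or-none)."""
        for i, a in enumerate(self.supernodes):
            for j in range(i, len(self.supernodes)):
                b = self.supernodes[j]
                present = sum(
                    1 for u in a for v in b
                    if u != v and binary_graph.has_edge(u, v)
                )
                expected = len(a) * len(b) if self.quotient.has_edge(i, j) else 0
                if i == j:
                    expected = 0  # supernode members are mutually non-adjacent
                if present != expected:
                    raise DomainError(
                        f"compression unsound between supernodes {i} and {j}: "
                        f"{present} of {len(a) * len(b)} edges present"
                    )


def compress(binary_graph: nx.Graph) -> CompressedGraph:
    """Group structurally identical nodes onto supernodes.

    Two nodes share a supernode iff their neighborhoods are identical; since
    the graphs carry no self-loops such nodes are automatically mutually
    non-adjacent.  The quotient adjacency is well defined because any member
    of a class sees any other class in an all-or-none fashion.
    """
    groups: dict[frozenset, list] = defaultdict(list)
    for node in binary_graph.nodes:
        groups[frozenset(binary_graph.neighbors(node))].append(node)
    supernodes = tuple(
        tuple(sorted(members, key=str))
        for members in sorted(groups.values(), key=lambda ms: str(min(ms, key=str)))
    )
    membership = {
        node: idx for idx, members in enumerate(supernodes) for node in members
    }
    quotient = nx.Graph()
    quotient.add_nodes_from(
        (idx, {"members": members, "size": len(members)})
        for idx, members in enumerate(supernodes)
    )
    for u, v in binary_graph.edges:
        i, j = membership[u], membership[v]
        if i != j:
            quotient.add_edge(i, j)
    return CompressedGraph(supernodes, membership, quotient)


# --------------------------------------------------------------------------- #
# graph statistics
# --------------------------------------------------------------------------- #

def _strengths(graph: nx.Graph) -> dict:
    return {
        node: sum(
            data.get("weight", 1.0) for _, _, data in graph.edges(node, data=True)
        )
        for node in graph.nodes
    }


def strength_centrality(graph: nx.Graph) -> dict:
    """Node strength (sum of incident weights) normalized by n-1, in [0, 1]."""
    n = graph.number_of_nodes()
    if n < 2:
        raise DomainError("strength centrality needs at least 2 nodes")
    return {node: s / (n - 1) for node, s in _strengths(graph).items()}


def network_centralization(graph: nx.Graph) -> float:
    """Freeman-style centralization of the normalized strengths:
    sum_i (c_max - c_i) / (n - 2).  1 for a binary star, 0 for any regular
    graph."""
    n = graph.number_of_nodes()
    if n < 3:
        raise DomainError("network centralization needs at least 3 nodes")
    centralities = strength_centrality(graph)
    c_max = max(centralities.values())
    return sum(c_max - c for c in centralities.values()) / (n - 2)


def clustering_coefficient(binary_graph: nx.Graph) -> tuple[dict, float]:
    """Watts-Strogatz local clustering per node (0 for degree < 2) and the
    network mean."""
    local = nx.clustering(binary_graph)
    mean = sum(local.values()) / len(local) if local else 0.0
    return local, mean


def attribute_assortativity(
    graph: nx.Graph,
    attributes: Mapping[str, float],
    weighted: bool = False,
) -> float:
    """Pearson correlation of a scalar node attribute across edge endpoints.

    Each edge is counted in both orientations; with ``weighted=True`` the
    edge weight acts as a multiplicity weight, so heavy edges dominate.
    Zero attribute variance over the edge ends makes the coefficient
    undefined and raises :class:`UndefinedStatisticError`.
    """
    missing = sorted(
        str(node) for node in graph.nodes
        if graph.degree(node) > 0 and node not in attributes
    )
    if missing:
        raise DomainError(f"attribute missing for connected nodes: {missing}")
    xs, ys, ws = [], [], []
    for u, v, data in graph.edges(data=True):
        w = data.get("weight", 1.0) if weighted else 1.0
        if w <= 0:
            continue
        xs.extend((attributes[u], attributes[v]))
        ys.extend((attributes[v], attributes[u]))
        ws.extend((w, w))
    if not xs:
        raise UndefinedStatisticError("assortativity undefined on an edgeless graph")
    x, y, w = np.asarray(xs), np.asarray(ys), np.asarray(ws)
    if np.ptp(x) == 0 or np.ptp(y) == 0:  # exact check, immune to round-off
        raise UndefinedStatisticError(
            "assortativity undefined: zero attribute variance over edges"
        )
    w = w / w.sum()
    mx, my = np.sum(w * x), np.sum(w * y)
    cov = np.sum(w * (x - mx) * (y - my))
    var_x = np.sum(w * (x - mx) ** 2)
    var_y = np.sum(w * (y - my) ** 2)
    return float(cov / np.sqrt(var_x * var_y))


def conservation_density(
    ordered_strains: Sequence[str],
    attributes: Mapping[str, float],
    window: int = 10,
    attr_threshold: float = 0.7,
) -> pd.DataFrame:
    """Fraction of strains per non-overlapping window whose attribute exceeds
    the threshold, as a percentage.

    ``ordered_strains`` is typically sorted by how frequently the strain is
    central across conditions; the trailing partial window is reported with
    its actual size.
    """
    rows = []
    for start in range(0, len(ordered_strains), window):
        chunk = ordered_strains[start:start + window]
        hits = sum(1 for s in chunk if attributes[s] > attr_threshold)
        rows.append(
            {
                "window_start": start,
                "size": len(chunk),
                "density_percent": 100.0 * hits / len(chunk),
            }
        )
    return pd.DataFrame(rows)


def write_edge_list(graph: nx.Graph, path: str | Path) -> None:
    """Tab-separated (strain_a, strain_b, weight) export."""
    rows = [
        (str(u), str(v), data.get("weight", 1.0))
        for u, v, data in graph.edges(data=True)
    ]
    frame = pd.DataFrame(sorted(rows), columns=["strain_a", "strain_b", "weight"])
    frame.to_csv(path, sep="\t", index=False)
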