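"""Candidate strain communities as cliques of the binary diversity graph.

A community of pairwise metabolically different strains is a clique: every
two members must differ enough in by-production (edge present) to have the
potential to exchange metabolites.  The maximum clique size is therefore the
upper bound of the metabolic diversity a condition supports.

Clique search is exact: maximum clique via branch-and-bound, maximal-clique
enumeration via pivoted Bron-Kerbosch (both through networkx, which
implements exactly these algorithms).  The graphs at hand are small and
heavily compressible, so exact search is cheap — especially on the quotient
graph, where each supernode of redundant strains collapses to one node and
is afterwards decompressed to a deterministic representative.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import networkx as nx

from .diversity_graph import CompressedGraph, compress
from .errors import DomainError

__all__ = [
    "Community",
    "max_clique",
    "enumerate_cliques",
    "cliques_via_compression",
]


@dataclass(frozen=True)
class Community:
    """A set of pairwise-adjacent strains (size >= 2) from one condition."""

    members: tuple
    condition_id: str = ""
    provenance: dict = field(default_factory=dict, compare=False, hash=False)

    def __post_init__(self):
        members = tuple(sorted(self.members, key=str))
        if len(set(members)) != len(members):
            raise DomainError("community members must be unique")
        if len(members) < 2:
            raise DomainError("a community needs at least 2 members")
        object.__setattr__(self, "members", members)

    @property
    def size(self) -> int:
        return len(self.members)

    def check_adjacency(self, binary_graph: nx.Graph) -> None:
        for u, v in itertools.combinations(self.members, 2):
            if not binary_graph.has_edge(u, v):
                raise DomainError(
                    f"community {self.members} is not a clique: {u}-{v} missing"
                )


def max_clique(binary_graph: nx.Graph) -> tuple[int, tuple]:
    """Exact maximum clique size and one witness clique.

    The witness is re-verified to be pairwise adjacent before returning.
    An empty graph has size 0.
    """
    if binary_graph.number_of_nodes() == 0:
        return 0, ()
    clique, size = nx.max_weight_clique(binary_graph, weight=None)
    witness = tuple(sorted(clique, key=str))
    for u, v in itertools.combinations(witness, 2):
        if not binary_graph.has_edge(u, v):
            raise DomainError(f"solver returned a non-clique witness: {u}-{v}")
    return int(size), witness


def enumerate_cliques(
    binary_graph: nx.Graph,
    min_size: int = 2,
    max_count: int | None = None,
    condition_id: str = "",
) -> tuple[list[Community], bool]:
    """All maximal cliques of at least ``min_size`` members, deterministically
    ordered (largest first, then lexicographic), optionally truncated at
    ``max_count`` with an explicit flag."""
    cliques = [
        tuple(sorted(c, key=str))
        for c in nx.find_cliques(binary_graph)
        if len(c) >= min_size
    ]
    cliques.sort(key=lambda c: (-len(c), tuple(str(m) for m in c)))
    truncated = max_count is not None and len(cliques) > max_count
    if truncated:
        cliques = cliques[:max_count]
    return (
        [Community(c, condition_id=condition_id) for c in cliques],
        truncated,
    )


def cliques_via_compression(
    binary_graph: nx.Graph,
    min_size: int = 2,
    expand_representatives: bool = False,
    max_count: int | None = None,
    condition_id: str = "",
) -> tuple[list[Community], CompressedGraph, bool]:
    """Find communities on the compressed graph and decompress.

    Supernode members are metabolically identical, hence mutually
    non-adjacent: a clique takes at most one strain per supernode, and which
    representative is chosen cannot affect a subsequent simulation.  By
    default the lexicographically smallest member represents its supernode
    (recorded in the community provenance for reproducibility);
    ``expand_representatives`` emits every member combination instead.
    """
    compressed = compress(binary_graph)
    quotient_cliques = [
        tuple(sorted(c))
        for c in nx.find_cliques(compressed.quotient)
        if len(c) >= min_size
    ]
    quotient_cliques.sort(key=lambda c: (-len(c), c))

    communities: list[Community] = []
    truncated = False
    for qc in quotient_cliques:
        classes = [compressed.supernodes[i] for i in qc]
        provenance = {
            "supernodes": tuple(qc),
            "class_sizes": tuple(len(c) for c in classes),
        }
        if expand_representatives:
            combos = itertools.product(*classes)
        else:
            combos = [tuple(cls[0] for cls in classes)]
        for members in combos:
            if max_count is not None and len(communities) >= max_count:
                truncated = True
                break
            community = Community(members, condition_id, dict(provenance))
            community.check_adjacency(binary_graph)
            communities.append(community)
        if truncated:
            break
    return communities, compressed, truncated
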