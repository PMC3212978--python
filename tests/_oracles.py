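"""Independent brute-force oracles shared by the test modules."""

import networkx as nx


def brute_force_cliques(graph: nx.Graph):
    """All cliques by explicit subset enumeration over bitmasks.

    Returns the maximum clique size and the set of maximal cliques
    (as frozensets).  ``clique[s]`` is built by dynamic programming on the
    lowest set bit, independent of any library clique routine.
    """
    nodes = sorted(graph.nodes)
    n = len(nodes)
    adj = [0] * n
    index = {v: i for i, v in enumerate(nodes)}
    for u, v in graph.edges:
        adj[index[u]] |= 1 << index[v]
        adj[index[v]] |= 1 << index[u]
    is_clique = [False] * (1 << n)
    is_clique[0] = True
    for s in range(1, 1 << n):
        v = (s & -s).bit_length() - 1
        rest = s & (s - 1)
        is_clique[s] = is_clique[rest] and (rest & ~adj[v]) == 0
    max_size = max(s.bit_count() for s in range(1 << n) if is_clique[s])
    maximal = []
    for s in range(1, 1 << n):
        if not is_clique[s]:
            continue
        extendable = any(
            is_clique[s | (1 << v)] for v in range(n) if not s & (1 << v)
        )
        if not extendable:
            maximal.append(frozenset(nodes[i] for i in range(n) if s & (1 << i)))
    return max_size, set(maximal)
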