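"""Degree-preserving network randomization and paired permutation ensembles.

The null model for the permutation tests keeps every node's degree fixed
while destroying the correlation between the two compared networks: each
network is rewired independently by repeated double-edge swaps, replacing
edges (a,b), (c,d) with (a,d), (c,b) whenever the swap creates neither a
self-loop nor a parallel edge.  Weights travel with the rewired edges
(weight(a,b) goes to (a,d), weight(c,d) to (c,b)), so the weight multiset
of the network is preserved and the weight- and rank-based edit cost
schemes remain applicable to rewired networks.

The swap loop is JIT-compiled with numba when available; the pure-Python
fallback produces bit-identical results from the same seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .networks import AlignedPair

logger = logging.getLogger(__name__)

__all__ = [
    "PermutationEnsemble",
    "member_seed",
    "rewire_degree_preserving",
    "generate_ensemble",
]

DEFAULT_SWAPS_PER_EDGE = 100

# adjacency-matrix swap kernel is used up to this node count
_DENSE_LIMIT = 20_000


def _swap_kernel(eu, ev, adj, pick, flip):  # pragma: no cover - thin loop
    """Apply attempted double-edge swaps in place on integer edge arrays.

    ``adj`` is the boolean adjacency matrix; ``pick[t]`` selects the two
    edge slots of attempt t and ``flip[t]`` the orientation of the second.
    """
    for t in range(pick.shape[0]):
        i = pick[t, 0]
        j = pick[t, 1]
        if i == j:
            continue
        a = eu[i]
        b = ev[i]
        c = eu[j]
        d = ev[j]
        if flip[t]:
            c, d = d, c
        # candidate replacement: (a,b),(c,d) -> (a,d),(c,b)
        if a == d or c == b:
            continue
        if adj[a, d] or adj[c, b]:
            continue
        if (a == c and d == b) or (a == b and d == c):
            continue  # both candidates are the same edge
        adj[a, b] = adj[b, a] = False
        adj[c, d] = adj[d, c] = False
        adj[a, d] = adj[d, a] = True
        adj[c, b] = adj[b, c] = True
        eu[i] = a
        ev[i] = d
        eu[j] = c
        ev[j] = b


try:  # compile the kernel when numba is present
    from numba import njit

    _swap_kernel_jit = njit(cache=False)(_swap_kernel)
except Exception:  # pragma: no cover - numba always present in practice
    _swap_kernel_jit = None


def member_seed(base_seed: int, network_index: int, member_index: int) -> int:
    """Deterministic per-network, per-member substream seed (< 2^31).

    Derived by feeding (base_seed, network_index, member_index) into a seed
    sequence, so ensembles are reproducible independently of the order in
    which members are generated.
    """
    ss = np.random.SeedSequence([int(base_seed), int(network_index), int(member_index)])
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


def rewire_degree_preserving(
    g: nx.Graph, swaps_per_edge: int = DEFAULT_SWAPS_PER_EDGE, seed: int = 0
) -> nx.Graph:
    """Randomize a simple network by attempted double-edge swaps.

    Performs ``swaps_per_edge * |E|`` swap attempts; an attempt draws two
    edges (a,b) and (c,d) (with the orientation of the second randomized)
    and replaces them with (a,d) and (c,b) unless that would create a
    self-loop or a parallel edge.  Node set, edge count and the exact
    degree sequence are preserved by construction; the weight multiset is
    preserved by the carriage rule.  Networks with fewer than two edges
    are returned unchanged (with a warning): no swap is possible.
    """
    if swaps_per_edge < 1:
        raise ValueError("swaps_per_edge must be >= 1")
    m = g.number_of_edges()
    if m < 2:
        logger.warning("rewire_degree_preserving: fewer than 2 edges, returning a copy")
        return g.copy()
    nodes = list(g.nodes)
    index = {u: k for k, u in enumerate(nodes)}
    n = len(nodes)
    if n > _DENSE_LIMIT:
        raise ValueError(f"networks above {_DENSE_LIMIT} nodes are not supported")
    eu = np.empty(m, dtype=np.int64)
    ev = np.empty(m, dtype=np.int64)
    weights = []
    adj = np.zeros((n, n), dtype=np.bool_)
    for k, (u, v, data) in enumerate(g.edges(data=True)):
        a, b = index[u], index[v]
        eu[k], ev[k] = a, b
        adj[a, b] = adj[b, a] = True
        weights.append(data.get("weight", 1.0))

    rng = np.random.default_rng(seed)
    attempts = swaps_per_edge * m
    pick = rng.integers(0, m, size=(attempts, 2))
    flip = rng.random(attempts) < 0.5
    kernel = _swap_kernel_jit if _swap_kernel_jit is not None else _swap_kernel
    kernel(eu, ev, adj, pick, flip)

    out = nx.Graph(**g.graph)
    out.add_nodes_from(g.nodes(data=True))
    for k in range(m):
        out.add_edge(nodes[eu[k]], nodes[ev[k]], weight=weights[k])
    return out


@dataclass
class PermutationEnsemble:
    """B independently rewired counterparts of one aligned network pair."""

    base_seed: int
    swaps_per_edge: int
    members: list[AlignedPair] = field(default_factory=list)

    @property
    def B(self) -> int:
        return len(self.members)


def generate_ensemble(
    pair: AlignedPair,
    B: int = 1000,
    base_seed: int = 0,
    swaps_per_edge: int = DEFAULT_SWAPS_PER_EDGE,
) -> PermutationEnsemble:
    """Generate B randomized pairs (G1^i, G2^i), fully seeded.

    Member i rewires G1 with the substream seed (base_seed, 1, i) and G2
    with (base_seed, 2, i); the whole ensemble is reproducible from
    ``base_seed`` alone.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    members = []
    for i in range(1, B + 1):
        g1r = rewire_degree_preserving(pair.g1, swaps_per_edge, member_seed(base_seed, 1, i))
        g2r = rewire_degree_preserving(pair.g2, swaps_per_edge, member_seed(base_seed, 2, i))
        members.append(AlignedPair(g1r, g2r))
    return PermutationEnsemble(base_seed, swaps_per_edge, members)
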