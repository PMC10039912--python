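"""Permutation statistics on graph edit distances and shortest-path proximity.

Empirical P-values follow the standard permutation-test convention with a
pseudo-count,

    P = (1 + #{i : GED(G1, G2) >= GED(G1^i, G2^i)}) / (1 + B),

so the attainable range is [1/(B+1), 1] and ties between the original and a
permuted distance count toward the numerator.  The same formula applies at
the node level (local distances) and the cluster level.  A one-sided
Mann-Whitney U test additionally asks whether the multiset of local
distances of the original pair is stochastically smaller than the pooled
local distances of the permuted pairs.

P-values are deliberately NOT adjusted for multiple testing: the analyses
these statistics serve draw their conclusions from the fraction of
non-significant results, which adjustment would inflate.  Reports carry an
explicit provenance flag to that effect.

Shortest-path proximity compares hop distances in a heterogeneous
drug-protein-protein-disease network between node pairs that are edges of
a reference network (X1) and all other evaluated pairs (X0), again with a
one-sided Mann-Whitney U test.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
from scipy.stats import mannwhitneyu

from .ged import cluster_ged, ged_profile, global_ged, local_ged, make_scheme
from .networks import AlignedPair
from .randomize import PermutationEnsemble, generate_ensemble

logger = logging.getLogger(__name__)

__all__ = [
    "ComparisonReport",
    "ShortestPathAnalysis",
    "empirical_p",
    "global_empirical_p",
    "local_empirical_p",
    "cluster_empirical_p",
    "mann_whitney_less",
    "mwu_local",
    "shortest_path_analysis",
    "compare",
]

# full permutation enumeration is used when C(n1+n2, n1) is at most this
_ENUMERATION_LIMIT = 20_000


def empirical_p(original: float, permuted: Sequence[float] | np.ndarray) -> float:
    """(1 + #{permuted <= original}) / (1 + B), the one-sided empirical P."""
    permuted = np.asarray(permuted, dtype=float)
    if permuted.size == 0:
        raise ValueError("need at least one permuted value")
    exceed = int(np.count_nonzero(original >= permuted))
    return (1 + exceed) / (1 + permuted.size)


def global_empirical_p(pair: AlignedPair, ensemble: PermutationEnsemble, kind: str = "uniform") -> float:
    """Empirical P for the global distance against the rewired ensemble."""
    orig = global_ged(pair, make_scheme(kind, pair))
    perm = [global_ged(m, make_scheme(kind, m)) for m in ensemble.members]
    return empirical_p(orig, perm)


def local_empirical_p(pair: AlignedPair, ensemble: PermutationEnsemble, u, kind: str = "uniform") -> float:
    """Node-specific empirical P based on local distances."""
    orig = local_ged(pair, u, make_scheme(kind, pair))
    perm = [local_ged(m, u, make_scheme(kind, m)) for m in ensemble.members]
    return empirical_p(orig, perm)


def cluster_empirical_p(
    pair: AlignedPair, ensemble: PermutationEnsemble, cluster: Iterable, kind: str = "uniform"
) -> float:
    """Cluster-level empirical P based on half-sums of local distances."""
    nodes = set(cluster)
    orig = cluster_ged(pair, nodes, make_scheme(kind, pair))
    perm = [cluster_ged(m, nodes, make_scheme(kind, m)) for m in ensemble.members]
    return empirical_p(orig, perm)


# --------------------------------------------------------------------------
# Mann-Whitney U
# --------------------------------------------------------------------------

def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    # pairwise count with half-credit for ties; small samples only
    u = 0.0
    for xi in x:
        u += np.count_nonzero(xi > y) + 0.5 * np.count_nonzero(xi == y)
    return u


def mann_whitney_less(x: Sequence[float], y: Sequence[float]) -> float:
    """One-sided MWU p-value for H1: x stochastically smaller than y.

    Uses full permutation enumeration when the number of group assignments
    C(n1+n2, n1) is small enough, scipy's exact U distribution for tie-free
    samples of moderate pooled size, and the tie-corrected normal
    approximation with continuity correction otherwise.  Degenerate input
    (every value identical) returns p = 1 with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = x.size, y.size
    if n1 < 1 or n2 < 1:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        logger.warning("mann_whitney_less: all values identical, p-value undefined; returning 1")
        return 1.0
    if math.comb(n1 + n2, n1) <= _ENUMERATION_LIMIT:
        u_obs = _u_statistic(x, y)
        count = 0
        total = 0
        idx = np.arange(n1 + n2)
        for subset in itertools.combinations(idx, n1):
            sx = pooled[list(subset)]
            sy = np.delete(pooled, list(subset))
            if _u_statistic(sx, sy) <= u_obs + 1e-12:
                count += 1
            total += 1
        return count / total
    has_ties = np.unique(pooled).size < pooled.size
    if not has_ties and n1 + n2 <= 200:
        return float(mannwhitneyu(x, y, alternative="less", method="exact").pvalue)
    return float(
        mannwhitneyu(x, y, alternative="less", method="asymptotic", use_continuity=True).pvalue
    )


def mwu_local(pair: AlignedPair, ensemble: PermutationEnsemble, kind: str = "uniform") -> float:
    """One-sided MWU: are the original local distances smaller than the
    pooled local distances of all permuted pairs?"""
    if len(pair.nodes) < 2:
        raise ValueError("need at least 2 nodes for the local MWU test")
    nodes = sorted(pair.nodes, key=str)
    orig = [local_ged(pair, u, make_scheme(kind, pair)) for u in nodes]
    perm: list[float] = []
    for m in ensemble.members:
        scheme = make_scheme(kind, m)
        perm.extend(local_ged(m, u, scheme) for u in nodes)
    return mann_whitney_less(orig, perm)


# --------------------------------------------------------------------------
# shortest-path proximity
# --------------------------------------------------------------------------

_PAIR_TYPES = {
    "disease-disease": ("disease", "disease"),
    "drug-drug": ("drug", "drug"),
    "drug-disease": ("drug", "disease"),
}


@dataclass(frozen=True)
class ShortestPathAnalysis:
    """X0/X1 split of hop distances and its one-sided MWU p-value.

    X1 holds distances of evaluated pairs that are edges of the reference
    network, X0 all other evaluated pairs; unreachable pairs are excluded
    from both and counted.
    """

    pair_type: str
    x0: list[int]
    x1: list[int]
    n_unreachable: int
    mwu_p: float


def shortest_path_analysis(
    hetero: nx.Graph, reference: nx.Graph, pair_type: str
) -> ShortestPathAnalysis:
    """Compare hop distances of reference-linked vs unlinked node pairs.

    Evaluates all unordered pairs of the requested node types whose
    endpoints occur in both the heterogeneous network and the reference
    network, splits the distance multiset by reference-edge membership and
    tests X1 < X0 with a one-sided MWU test.
    """
    try:
        type_a, type_b = _PAIR_TYPES[pair_type]
    except KeyError:
        raise ValueError(f"unknown pair type {pair_type!r}; expected one of {sorted(_PAIR_TYPES)}") from None
    ref_nodes = set(reference.nodes)
    nodes_a = sorted(
        (n for n, d in hetero.nodes(data=True) if d.get("type") == type_a and n in ref_nodes),
        key=str,
    )
    if type_a == type_b:
        pairs = list(itertools.combinations(nodes_a, 2))
        sources = nodes_a[:-1] if nodes_a else []
    else:
        nodes_b = sorted(
            (n for n, d in hetero.nodes(data=True) if d.get("type") == type_b and n in ref_nodes),
            key=str,
        )
        pairs = [(a, b) for a in nodes_a for b in nodes_b]
        sources = nodes_a if len(nodes_a) <= len(nodes_b) else nodes_b
    if not pairs:
        raise ValueError("no evaluated node pairs (check node types and reference overlap)")

    dist_from: dict = {
        s: nx.single_source_shortest_path_length(hetero, s) for s in sources
    }
    x0: list[int] = []
    x1: list[int] = []
    unreachable = 0
    for a, b in pairs:
        if a in dist_from:
            d = dist_from[a].get(b)
        else:
            d = dist_from[b].get(a)
        if d is None:
            unreachable += 1
            continue
        if reference.has_edge(a, b):
            x1.append(d)
        else:
            x0.append(d)
    if not x1:
        raise ValueError("X1 empty: no evaluated pair is a reference edge")
    if not x0:
        raise ValueError("X0 empty: every evaluated pair is a reference edge")
    p = mann_whitney_less(x1, x0)
    return ShortestPathAnalysis(pair_type, x0, x1, unreachable, p)


# --------------------------------------------------------------------------
# full comparison of one network pair
# --------------------------------------------------------------------------

@dataclass
class ComparisonReport:
    """All distances and P-values for one aligned network pair.

    ``local`` maps node -> (local distance, local empirical P) and
    ``clusters`` maps cluster id -> (cluster distance, cluster empirical P).
    ``provenance`` records seeds and parameters; ``adjusted`` is always
    False — P-values are reported unadjusted by design.
    """

    kind: str
    B: int
    global_ged: float
    global_empirical_p: float
    local: dict
    mwu_p: float
    clusters: dict | None = None
    adjusted: bool = False
    provenance: dict = field(default_factory=dict)

    def summary(self) -> dict:
        return {
            "scheme": self.kind,
            "B": self.B,
            "global_ged": self.global_ged,
            "global_empirical_p": self.global_empirical_p,
            "mwu_p": self.mwu_p,
            "clusters": self.clusters,
            "n_nodes": len(self.local),
            "p_values_adjusted": self.adjusted,
            "provenance": self.provenance,
        }


def compare(
    pair: AlignedPair,
    kind: str = "uniform",
    B: int = 1000,
    base_seed: int = 0,
    swaps_per_edge: int = 100,
    clusters: Mapping[str, Iterable] | None = None,
    ensemble: PermutationEnsemble | None = None,
) -> ComparisonReport:
    """Run the full permutation comparison of one aligned network pair.

    Generates (or reuses) the rewired ensemble, computes local/global/
    cluster distances for the original and every permuted pair, and derives
    the empirical P-values and the local MWU p-value in a single pass over
    the ensemble.
    """
    if ensemble is None:
        ensemble = generate_ensemble(pair, B, base_seed, swaps_per_edge)
    B = ensemble.B
    nodes = sorted(pair.nodes, key=str)
    prof = ged_profile(pair, kind, clusters)
    orig_local = np.array([prof.local[u] for u in nodes])

    perm_local = np.empty((B, len(nodes)))
    for i, m in enumerate(ensemble.members):
        scheme = make_scheme(kind, m)
        perm_local[i] = [local_ged(m, u, scheme) for u in nodes]
    perm_global = perm_local.sum(axis=1) / 2.0

    global_p = empirical_p(prof.global_, perm_global)
    local = {
        u: (float(orig_local[k]), empirical_p(orig_local[k], perm_local[:, k]))
        for k, u in enumerate(nodes)
    }
    cluster_table = None
    if clusters is not None:
        node_index = {u: k for k, u in enumerate(nodes)}
        cluster_table = {}
        for name, members in clusters.items():
            cols = [node_index[u] for u in set(members)]
            perm_c = perm_local[:, cols].sum(axis=1) / 2.0
            cluster_table[name] = (prof.clusters[name], empirical_p(prof.clusters[name], perm_c))
    mwu_p = mann_whitney_less(orig_local, perm_local.ravel())

    return ComparisonReport(
        kind=kind,
        B=B,
        global_ged=prof.global_,
        global_empirical_p=global_p,
        local=local,
        mwu_p=mwu_p,
        clusters=cluster_table,
        adjusted=False,
        provenance={
            "base_seed": ensemble.base_seed,
            "swaps_per_edge": ensemble.swaps_per_edge,
            "B": B,
            "scheme": kind,
        },
    )
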