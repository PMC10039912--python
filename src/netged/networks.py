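"""Construction of diseasomes, drugomes and drug-disease networks.

Five network types are supported:

* Jaccard networks — diseases (or drugs) connected when their annotation
  sets overlap, with weight ``|Ai ∩ Aj| / |Ai ∪ Aj|``;
* comorbidity networks — diseases connected when their co-occurrence across
  patient records is significant by a one-tailed Fisher exact test after
  Benjamini-Hochberg correction, weighted by the phi correlation;
* bipartite drug-disease indication networks, read directly off the data;
* bipartite target-based drug-disease networks (drug targets a protein
  encoded by a disease-associated gene);
* heterogeneous drug-protein-protein-disease networks for shortest-path
  proximity analyses.

Before any pairwise comparison, two networks over the same vocabulary are
aligned, i.e. restricted to their common node set, so that the graph edit
distance can be computed under the identity node map.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .io_formats import AssociationTable, DiagnosisRecords

logger = logging.getLogger(__name__)

__all__ = [
    "AlignedPair",
    "build_jaccard_network",
    "phi_correlation",
    "comorbidity_p_value",
    "build_comorbidity_network",
    "build_bipartite_indication_network",
    "build_target_based_drug_disease",
    "assemble_heterogeneous_network",
    "align_networks",
]


@dataclass(frozen=True)
class AlignedPair:
    """Two networks restricted to one common node set.

    With identical node sets the optimal node map of the edit distance is
    fixed to the identity, so only edge edit operations remain.
    """

    g1: nx.Graph
    g2: nx.Graph

    def __post_init__(self) -> None:
        if set(self.g1.nodes) != set(self.g2.nodes):
            raise ValueError("aligned networks must share one node set")
        if self.g1.number_of_nodes() == 0:
            raise ValueError("aligned node set is empty")

    @property
    def nodes(self) -> set:
        return set(self.g1.nodes)


def build_jaccard_network(table: AssociationTable, min_shared: int = 1) -> nx.Graph:
    """Jaccard-index network over the entities of an association table.

    Entities i and j are connected iff they share at least ``min_shared``
    annotations; the edge weight is the Jaccard index of their annotation
    sets.  Entities with empty annotation sets were already removed during
    table cleaning (missing data), so every entity becomes a node.
    """
    if min_shared < 1:
        raise ValueError("min_shared must be >= 1")
    if not table.entries:
        raise ValueError("association table is empty")
    g = nx.Graph(vocabulary=table.entity_vocabulary)
    g.add_nodes_from(table.entries)
    # inverted index: annotation -> entities, to only touch co-annotated pairs
    by_annotation: dict[str, list[str]] = {}
    for entity, anns in table.entries.items():
        for a in anns:
            by_annotation.setdefault(a, []).append(entity)
    shared: dict[tuple[str, str], int] = {}
    for entities in by_annotation.values():
        entities.sort()
        for i, j in itertools.combinations(entities, 2):
            shared[(i, j)] = shared.get((i, j), 0) + 1
    for (i, j), n_shared in shared.items():
        if n_shared >= min_shared:
            union = len(table.entries[i] | table.entries[j])
            g.add_edge(i, j, weight=n_shared / union)
    return g


def phi_correlation(Ii: int, Ij: int, Cij: int, N: int) -> float:
    """Phi correlation of two diseases from incidences and co-occurrence.

    Equals the Pearson correlation of the two binary diagnosis indicator
    vectors across the N patients; positive iff the diseases co-occur more
    often than expected under independence.
    """
    _check_comorbidity_counts(Ii, Ij, Cij, N)
    num = Cij * N - Ii * Ij
    den = math.sqrt(Ii * Ij * (N - Ii) * (N - Ij))
    return num / den


def comorbidity_p_value(Ii: int, Ij: int, Cij: int, N: int) -> float:
    """One-tailed (over-representation) Fisher exact p-value.

    The co-occurrence count under independence is hypergeometric with
    population N, Ii successes and Ij draws; the p-value is the upper tail
    P(X >= Cij).
    """
    _check_comorbidity_counts(Ii, Ij, Cij, N)
    return float(hypergeom.sf(Cij - 1, N, Ii, Ij))


def _check_comorbidity_counts(Ii: int, Ij: int, Cij: int, N: int) -> None:
    if N < 1:
        raise ValueError("N must be >= 1")
    if not (0 < Ii < N) or not (0 < Ij < N):
        raise ValueError(
            f"incidences must satisfy 0 < I < N (got Ii={Ii}, Ij={Ij}, N={N}): "
            "phi correlation has an undefined denominator otherwise"
        )
    if not (0 <= Cij <= min(Ii, Ij)):
        raise ValueError(f"co-occurrence Cij={Cij} outside [0, min(Ii, Ij)]")


def build_comorbidity_network(records: DiagnosisRecords, alpha: float = 0.05) -> nx.Graph:
    """Comorbidity network from harmonized diagnosis records.

    Every unordered disease pair is tested with the one-tailed Fisher exact
    test; Benjamini-Hochberg correction is applied across all tested pairs
    (including never-co-occurring ones, which have p = 1 — the conservative
    choice of testing family).  Diseases i and j are connected iff the
    adjusted p-value is <= ``alpha`` and the phi correlation is positive;
    the edge weight is the phi correlation.
    """
    diseases = sorted({c for codes in records.patients.values() for c in codes})
    if len(diseases) < 2:
        raise ValueError("need at least 2 diseases to build a comorbidity network")
    N = records.N
    idx = {d: k for k, d in enumerate(diseases)}
    X = np.zeros((N, len(diseases)), dtype=np.int8)
    for row, codes in enumerate(records.patients.values()):
        for c in codes:
            X[row, idx[c]] = 1
    I = X.sum(axis=0).astype(np.int64)
    # diseases present in every patient have a vanishing phi denominator
    testable = I < N
    if not np.all(testable):
        logger.warning(
            "excluding %d diseases with incidence N from comorbidity testing",
            int((~testable).sum()),
        )
    C = X.T.astype(np.int64) @ X.astype(np.int64)

    ii, jj = np.triu_indices(len(diseases), k=1)
    keep = testable[ii] & testable[jj]
    ii, jj = ii[keep], jj[keep]
    if ii.size == 0:
        raise ValueError("no testable disease pairs")
    cij = C[ii, jj]
    Ii, Ij = I[ii], I[jj]
    pvals = hypergeom.sf(cij - 1, N, Ii, Ij)
    adjusted = multipletests(pvals, method="fdr_bh")[1]
    phi = (cij * N - Ii * Ij) / np.sqrt(
        Ii.astype(float) * Ij * (N - Ii) * (N - Ij)
    )

    g = nx.Graph(vocabulary="ICD-10")
    g.add_nodes_from(diseases)
    for k in np.flatnonzero((adjusted <= alpha) & (phi > 0)):
        g.add_edge(diseases[ii[k]], diseases[jj[k]], weight=float(phi[k]))
    return g


def build_bipartite_indication_network(indications: AssociationTable) -> nx.Graph:
    """Unweighted bipartite drug-disease network from an indication table.

    ``indications`` maps each drug to the diseases it is indicated for.
    Drugs without indications were removed during table cleaning.
    """
    g = nx.Graph(vocabulary=indications.annotation_type)
    for drug, diseases in indications.entries.items():
        if drug in diseases:
            raise ValueError(f"id collision between drug and disease: {drug!r}")
        g.add_node(drug, type="drug")
        for disease in diseases:
            g.add_node(disease, type="disease")
            g.add_edge(drug, disease, weight=1.0)
    return g


def build_target_based_drug_disease(
    drug_targets: AssociationTable,
    gene_protein: AssociationTable,
    disease_genes: AssociationTable,
) -> nx.Graph:
    """Bipartite drug-disease network via shared target proteins.

    A disease i is connected to a drug j iff j targets a protein encoded by
    a gene associated with i.  Edges are unweighted; the graph is simple,
    so several shared targets still yield a single edge.
    """
    encodes = gene_protein.entries
    disease_proteins: dict[str, set[str]] = {}
    for disease, genes in disease_genes.entries.items():
        proteins: set[str] = set()
        for gene in genes:
            proteins |= encodes.get(gene, set())
        disease_proteins[disease] = proteins
    g = nx.Graph(vocabulary=disease_genes.entity_vocabulary)
    for drug, targets in drug_targets.entries.items():
        g.add_node(drug, type="drug")
        for disease, proteins in disease_proteins.items():
            if drug == disease:
                raise ValueError(f"id collision between drug and disease: {drug!r}")
            if proteins & targets:
                g.add_node(disease, type="disease")
                g.add_edge(drug, disease, weight=1.0)
    for disease in disease_proteins:
        g.add_node(disease, type="disease")
    return g


def assemble_heterogeneous_network(
    disease_genes: AssociationTable,
    ppi: AssociationTable,
    drug_targets: AssociationTable,
    gene_protein: AssociationTable,
) -> nx.Graph:
    """Typed drug-protein-protein-disease network.

    Drugs connect to their target proteins, proteins connect through
    protein-protein interactions, and diseases connect to the proteins
    encoded by their associated genes.  Edges are unweighted; shortest
    paths on this graph are hop counts.
    """
    g = nx.Graph(vocabulary=disease_genes.entity_vocabulary)
    types: dict[str, str] = {}

    def add(node: str, ntype: str) -> None:
        prev = types.get(node)
        if prev is not None and prev != ntype:
            raise ValueError(f"id collision across types: {node!r} is both {prev} and {ntype}")
        types[node] = ntype
        g.add_node(node, type=ntype)

    encodes = gene_protein.entries
    for disease, genes in disease_genes.entries.items():
        add(disease, "disease")
        for gene in genes:
            for protein in encodes.get(gene, set()):
                add(protein, "protein")
                g.add_edge(disease, protein, weight=1.0)
    for p, partners in ppi.entries.items():
        add(p, "protein")
        for q in partners:
            if p == q:
                continue
            add(q, "protein")
            g.add_edge(p, q, weight=1.0)
    for drug, targets in drug_targets.entries.items():
        add(drug, "drug")
        for protein in targets:
            add(protein, "protein")
            g.add_edge(drug, protein, weight=1.0)
    return g


def align_networks(g1: nx.Graph, g2: nx.Graph) -> AlignedPair:
    """Restrict two networks to their common node set.

    Edges with an endpoint outside the intersection are removed; weights
    are preserved.  Idempotent, and symmetric in the resulting node set.
    """
    v1, v2 = g1.graph.get("vocabulary"), g2.graph.get("vocabulary")
    if v1 is not None and v2 is not None and v1 != v2:
        raise ValueError(f"cannot align networks over different vocabularies: {v1!r} vs {v2!r}")
    common = set(g1.nodes) & set(g2.nodes)
    if not common:
        raise ValueError("aligned node set is empty (disjoint networks)")
    dropped = (g1.number_of_nodes() - len(common)) + (g2.number_of_nodes() - len(common))
    if dropped:
        logger.info("align_networks: dropped %d nodes outside the common set", dropped)
    return AlignedPair(g1.subgraph(common).copy(), g2.subgraph(common).copy())
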