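"""Synthetic benchmark harness used by the test suite and acceptance script.

These helpers compose the synthetic generators into the standard evaluation
setups: pairs of independent random networks for oracle checks, Jaccard
network pairs with planted mechanism overlap for calibration and power
studies, and a planted heterogeneous drug-protein-protein-disease setting
for shortest-path proximity analyses.
"""

from __future__ import annotations

import itertools

import numpy as np

from .io_formats import AssociationTable
from .networks import AlignedPair, align_networks, assemble_heterogeneous_network, build_jaccard_network
from .stats import ShortestPathAnalysis, shortest_path_analysis
from .synth import MechanismModel, simulate_association_pair, simulate_random_network

__all__ = [
    "random_aligned_pair",
    "mechanism_network_pair",
    "proximity_benchmark",
]


def random_aligned_pair(n_nodes: int, n_edges: int, seed: int) -> AlignedPair:
    """Two independent uniform random networks on one node set."""
    g1 = simulate_random_network(n_nodes, n_edges, "uniform", seed)
    g2 = simulate_random_network(n_nodes, n_edges, "uniform", seed + 1_000_003)
    return AlignedPair(g1, g2)


def mechanism_network_pair(rho: float, seed: int, **model_kwargs) -> AlignedPair:
    """Aligned Jaccard networks from a simulated association-table pair."""
    model = MechanismModel(rho=rho, seed=seed, **model_kwargs)
    t1, t2 = simulate_association_pair(model)
    return align_networks(build_jaccard_network(t1), build_jaccard_network(t2))


def proximity_benchmark(rho: float, seed: int) -> ShortestPathAnalysis:
    """Shortest-path proximity analysis on a planted heterogeneous network.

    Diseases draw genes from latent mechanisms (first data type); each gene
    encodes one protein, proteins are wired by a random PPI layer, and a
    few drugs target random proteins.  The reference diseasome is the
    Jaccard network of the second data type, so at high ``rho`` its edges
    connect diseases that share proteins in the heterogeneous network
    (distance 2), while at ``rho = 0`` the reference is independent of the
    disease-protein layer.
    """
    model = MechanismModel(
        n_entities=40, n_mechanisms=8, pool_size=6, rho=rho, noise_rate=1, seed=seed
    )
    disease_genes, reference_table = simulate_association_pair(model)
    genes = sorted({a for anns in disease_genes.entries.values() for a in anns})
    gene_protein = AssociationTable(
        disease_genes.annotation_type, "protein", {g: {"p_" + g} for g in genes}
    )
    proteins = ["p_" + g for g in genes]
    rng = np.random.default_rng(seed + 77)
    all_pairs = list(itertools.combinations(range(len(proteins)), 2))
    ppi_entries: dict[str, set[str]] = {}
    for k in rng.choice(len(all_pairs), size=min(120, len(all_pairs)), replace=False):
        i, j = all_pairs[k]
        ppi_entries.setdefault(proteins[i], set()).add(proteins[j])
    ppi = AssociationTable("protein", "protein", ppi_entries)
    drug_targets = AssociationTable(
        "drug",
        "protein",
        {f"drug{d}": set(rng.choice(proteins, size=3, replace=False)) for d in range(4)},
    )
    hetero = assemble_heterogeneous_network(disease_genes, ppi, drug_targets, gene_protein)
    reference = build_jaccard_network(reference_table)
    return shortest_path_analysis(hetero, reference, "disease-disease")
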