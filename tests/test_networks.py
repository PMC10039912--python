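import math

import numpy as np
import pytest
from scipy.stats import pearsonr

from netged import (
    AssociationTable,
    DiagnosisRecords,
    align_networks,
    assemble_heterogeneous_network,
    build_bipartite_indication_network,
    build_comorbidity_network,
    build_jaccard_network,
    build_target_based_drug_disease,
    comorbidity_p_value,
    phi_correlation,
)
from netged.synth import ComorbidityModel, simulate_patient_records

from conftest import graph_from_edges


def indicator_phi(Ii, Ij, Cij, N):
    """Pearson correlation of the two binary patient-indicator vectors."""
    x = np.zeros(N)
    y = np.zeros(N)
    x[:Ii] = 1
    y[:Cij] = 1
    y[Ii:Ii + Ij - Cij] = 1
    return pearsonr(x, y)[0]


def hypergeom_tail(Ii, Ij, Cij, N):
    """Exhaustive upper-tail sum of the hypergeometric pmf."""
    total = math.comb(N, Ij)
    return sum(
        math.comb(Ii, k) * math.comb(N - Ii, Ij - k) for k in range(Cij, min(Ii, Ij) + 1)
    ) / total


class TestJaccardNetwork:
    def test_edge_weight_is_jaccard_index(self):
        table = AssociationTable("disease", "gene", {"d1": {"g1", "g2"}, "d2": {"g2", "g3"}, "d3": {"g4"}})
        g = build_jaccard_network(table)
        assert set(g.nodes) == {"d1", "d2", "d3"}
        assert set(map(frozenset, g.edges)) == {frozenset({"d1", "d2"})}
        assert g.edges["d1", "d2"]["weight"] == pytest.approx(1 / 3)

    def test_identical_annotation_sets_have_weight_one(self):
        table = AssociationTable("disease", "gene", {"d1": {"g1"}, "d2": {"g1"}})
        assert build_jaccard_network(table).edges["d1", "d2"]["weight"] == 1.0

    def test_min_shared_raises_edge_threshold(self):
        table = AssociationTable("disease", "gene", {"d1": {"g1", "g2"}, "d2": {"g2", "g3"}})
        assert build_jaccard_network(table, min_shared=2).number_of_edges() == 0

    def test_min_shared_below_one_is_an_error(self):
        with pytest.raises(ValueError):
            build_jaccard_network(AssociationTable("d", "g", {"d1": {"g1"}}), min_shared=0)

    def test_weights_in_unit_interval(self):
        rng = np.random.default_rng(0)
        entries = {
            f"d{i}": set(rng.choice(30, size=rng.integers(1, 8), replace=False).astype(str))
            for i in range(25)
        }
        g = build_jaccard_network(AssociationTable("disease", "gene", entries))
        for _, _, w in g.edges(data="weight"):
            assert 0 < w <= 1


class TestPhiCorrelation:
    @pytest.mark.parametrize(
        "Ii,Ij,Cij,N,expected",
        [
            (50, 50, 25, 100, 0.0),
            (10, 10, 10, 100, 1.0),
            (10, 20, 5, 200, 0.305887645160749),  # frozen from the indicator oracle
        ],
    )
    def test_matches_frozen_values(self, Ii, Ij, Cij, N, expected):
        assert phi_correlation(Ii, Ij, Cij, N) == pytest.approx(expected, abs=1e-12)

    def test_equals_pearson_of_indicator_vectors(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            N = int(rng.integers(10, 500))
            Ii = int(rng.integers(1, N))
            Ij = int(rng.integers(1, N))
            lo = max(0, Ii + Ij - N)
            Cij = int(rng.integers(lo, min(Ii, Ij) + 1))
            assert phi_correlation(Ii, Ij, Cij, N) == pytest.approx(
                indicator_phi(Ii, Ij, Cij, N), abs=1e-9
            )

    def test_symmetric_in_the_two_diseases(self):
        assert phi_correlation(10, 20, 5, 200) == phi_correlation(20, 10, 5, 200)

    @pytest.mark.parametrize("Ii", [0, 100])
    def test_degenerate_incidence_is_an_error(self, Ii):
        with pytest.raises(ValueError):
            phi_correlation(Ii, 10, 0, 100)


class TestComorbidityPValue:
    @pytest.mark.parametrize(
        "Ii,Ij,Cij,N,expected",
        [
            (5, 5, 0, 10, 1.0),
            (5, 5, 5, 10, 1 / 252),
            (10, 10, 8, 20, 2126 / 184756),
        ],
    )
    def test_matches_hypergeometric_tail(self, Ii, Ij, Cij, N, expected):
        assert comorbidity_p_value(Ii, Ij, Cij, N) == pytest.approx(expected, rel=1e-12)

    def test_agrees_with_exhaustive_enumeration(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            N = int(rng.integers(5, 50))
            Ii = int(rng.integers(1, N))
            Ij = int(rng.integers(1, N))
            lo = max(0, Ii + Ij - N)
            Cij = int(rng.integers(lo, min(Ii, Ij) + 1))
            assert comorbidity_p_value(Ii, Ij, Cij, N) == pytest.approx(
                hypergeom_tail(Ii, Ij, Cij, N), rel=1e-9
            )


class TestComorbidityNetwork:
    def test_planted_pair_weight_matches_closed_form(self):
        # ~200 of 1,000 patients carry both diseases, each at incidence ~250
        model = ComorbidityModel(
            n_patients=1000,
            prevalences={"A00": 0.25, "A01": 0.25, "B00": 0.05, "B01": 0.05},
            planted=(("A00", "A01", 3.2),),
            seed=11,
        )
        records = simulate_patient_records(model)
        g = build_comorbidity_network(records)
        assert g.has_edge("A00", "A01")
        inc = records.incidences()
        cij = sum(1 for s in records.patients.values() if {"A00", "A01"} <= s)
        expected = phi_correlation(inc["A00"], inc["A01"], cij, records.N)
        assert g.edges["A00", "A01"]["weight"] == pytest.approx(expected, abs=1e-12)

    def test_never_cooccurring_pair_has_no_edge(self):
        patients = {f"p{i}": {"A00"} for i in range(10)}
        patients.update({f"q{i}": {"A01"} for i in range(10)})
        patients.update({f"r{i}": set() for i in range(10)})
        g = build_comorbidity_network(DiagnosisRecords(patients))
        assert not g.has_edge("A00", "A01")

    def test_invariant_to_patient_ordering(self):
        model = ComorbidityModel(
            n_patients=500,
            prevalences={c: 0.2 for c in ("A00", "A01", "A02", "A03")},
            planted=(("A00", "A01", 2.5),),
            seed=3,
        )
        records = simulate_patient_records(model)
        reordered = DiagnosisRecords(dict(reversed(list(records.patients.items()))))
        g1, g2 = build_comorbidity_network(records), build_comorbidity_network(reordered)
        assert set(map(frozenset, g1.edges)) == set(map(frozenset, g2.edges))

    def test_fewer_than_two_diseases_is_an_error(self):
        with pytest.raises(ValueError):
            build_comorbidity_network(DiagnosisRecords({"p0": {"A00"}, "p1": {"A00"}}))


class TestBipartiteNetworks:
    def test_indication_edges_and_types(self):
        table = AssociationTable("drug", "disease", {"j": {"i"}, "k": {"i", "i2"}})
        g = build_bipartite_indication_network(table)
        assert g.has_edge("j", "i") and g.has_edge("k", "i2")
        assert g.nodes["j"]["type"] == "drug" and g.nodes["i"]["type"] == "disease"
        same_type = [
            (u, v) for u, v in g.edges if g.nodes[u]["type"] == g.nodes[v]["type"]
        ]
        assert not same_type

    def test_target_based_join(self):
        disease_genes = AssociationTable("disease", "gene", {"i": {"g", "g2"}, "i2": {"g3"}})
        gene_protein = AssociationTable("gene", "protein", {"g": {"p"}, "g2": {"p"}, "g3": {"p3"}})
        drug_targets = AssociationTable("drug", "protein", {"j": {"p"}})
        g = build_target_based_drug_disease(drug_targets, gene_protein, disease_genes)
        # two genes of i encode the same target -> still a single simple edge
        assert list(map(frozenset, g.edges)) == [frozenset({"i", "j"})]
        assert not g.has_edge("i2", "j")


class TestHeterogeneousNetwork:
    def build(self):
        disease_genes = AssociationTable("disease", "gene", {"i": {"g"}})
        gene_protein = AssociationTable("gene", "protein", {"g": {"p"}})
        ppi = AssociationTable("protein", "protein", {"p": {"q"}, "q": {"p"}})
        drug_targets = AssociationTable("drug", "protein", {"j": {"p"}, "lonely": {"z"}})
        return assemble_heterogeneous_network(disease_genes, ppi, drug_targets, gene_protein)

    def test_disease_drug_path_through_shared_target(self):
        import networkx as nx

        g = self.build()
        assert nx.shortest_path_length(g, "i", "j") == 2
        assert not nx.has_path(g, "i", "lonely")

    def test_duplicate_ppi_edges_collapse(self):
        g = self.build()
        assert g.number_of_edges("p", "q") == 1

    def test_id_collision_across_types_is_an_error(self):
        disease_genes = AssociationTable("disease", "gene", {"x": {"g"}})
        gene_protein = AssociationTable("gene", "protein", {"g": {"x"}})
        ppi = AssociationTable("protein", "protein", {})
        drug_targets = AssociationTable("drug", "protein", {})
        with pytest.raises(ValueError, match="collision"):
            assemble_heterogeneous_network(disease_genes, ppi, drug_targets, gene_protein)


class TestAlignNetworks:
    def test_restricts_to_common_node_set(self):
        g1 = graph_from_edges("abc", [("a", "b"), ("b", "c")])
        g2 = graph_from_edges("bcd", [("b", "c"), ("c", "d")])
        pair = align_networks(g1, g2)
        assert pair.nodes == {"b", "c"}
        assert set(map(frozenset, pair.g1.edges)) == {frozenset({"b", "c"})}

    def test_identical_node_sets_unchanged_and_idempotent(self):
        g1 = graph_from_edges("abc", [("a", "b")])
        g2 = graph_from_edges("abc", [("b", "c")])
        pair = align_networks(g1, g2)
        again = align_networks(pair.g1, pair.g2)
        assert pair.nodes == again.nodes == {"a", "b", "c"}

    def test_commutative_in_node_set_terms(self):
        g1 = graph_from_edges("abc", [("a", "b")])
        g2 = graph_from_edges("bcd", [("c", "d")])
        assert align_networks(g1, g2).nodes == align_networks(g2, g1).nodes

    def test_disjoint_node_sets_error(self):
        with pytest.raises(ValueError):
            align_networks(graph_from_edges("ab", [("a", "b")]), graph_from_edges("cd", [("c", "d")]))

    def test_vocabulary_mismatch_error(self):
        g1 = graph_from_edges("ab", [("a", "b")], vocabulary="mondo")
        g2 = graph_from_edges("ab", [("a", "b")], vocabulary="icd10")
        with pytest.raises(ValueError, match="vocabular"):
            align_networks(g1, g2)
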