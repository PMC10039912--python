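import itertools

import numpy as np
import pytest
from scipy.stats import rankdata

from netged import (
    AlignedPair,
    cluster_empirical_p,
    empirical_p,
    global_empirical_p,
    local_empirical_p,
    mann_whitney_less,
    mwu_local,
    shortest_path_analysis,
)
from netged.randomize import PermutationEnsemble, generate_ensemble

from conftest import graph_from_edges, six_cycle, star_pair, two_triangles


def handmade_ensemble(members, base_seed=0):
    return PermutationEnsemble(base_seed=base_seed, swaps_per_edge=0, members=members)


def mwu_oracle(x, y):
    """Exact permutation p-value via midrank sums (independent formulation)."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    n1 = x.size
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    count = total = 0
    for subset in itertools.combinations(range(pooled.size), n1):
        u = ranks[list(subset)].sum() - n1 * (n1 + 1) / 2
        count += u <= u_obs + 1e-12
        total += 1
    return count / total


class TestEmpiricalP:
    def test_formula_counts_ties_as_exceedances(self):
        assert empirical_p(2.0, [3.0, 1.0, 2.0, 5.0]) == 3 / 5
        assert empirical_p(0.0, [1.0] * 1000) == pytest.approx(1 / 1001)
        assert empirical_p(9.0, [1.0, 2.0]) == 1.0

    def test_floor_attained_when_original_beats_every_permutation(self):
        # identical six-cycles (distance 0) against members forced apart
        pair = AlignedPair(six_cycle(), six_cycle())
        members = [AlignedPair(two_triangles(), six_cycle()) for _ in range(1000)]
        p = global_empirical_p(pair, handmade_ensemble(members))
        assert p == pytest.approx(1 / 1001)

    def test_p_one_when_degree_sequence_forces_the_null(self, star_pair):
        # a star is the unique graph with its degree sequence, so every
        # rewired pair ties with the original at distance zero
        ensemble = generate_ensemble(star_pair, B=19, base_seed=1, swaps_per_edge=10)
        assert global_empirical_p(star_pair, ensemble) == 1.0
        assert local_empirical_p(star_pair, ensemble, "a") == 1.0

    def test_local_floor_for_preserved_neighborhood(self):
        pair = AlignedPair(six_cycle(), six_cycle())
        members = [AlignedPair(two_triangles(), six_cycle()) for _ in range(9)]
        # node 1's neighborhoods are identical originally but differ in all
        # permuted pairs
        assert local_empirical_p(pair, handmade_ensemble(members), "1") == 1 / 10
        assert cluster_empirical_p(pair, handmade_ensemble(members), {"1"}) == 1 / 10

    def test_isolated_node_under_degree_preserving_null_has_p_one(self):
        g1 = graph_from_edges("abcde", [("a", "b"), ("b", "c"), ("c", "d"), ("d", "a")])
        g2 = graph_from_edges("abcde", [("a", "c"), ("c", "b"), ("b", "d"), ("d", "a")])
        pair = AlignedPair(g1, g2)
        ensemble = generate_ensemble(pair, B=20, base_seed=3, swaps_per_edge=10)
        assert local_empirical_p(pair, ensemble, "e") == 1.0

    def test_cluster_of_all_nodes_equals_global(self):
        pair = AlignedPair(six_cycle(), two_triangles())
        ensemble = generate_ensemble(pair, B=20, base_seed=5, swaps_per_edge=20)
        assert cluster_empirical_p(pair, ensemble, pair.nodes) == global_empirical_p(pair, ensemble)

    def test_all_empirical_ps_within_bounds(self):
        pair = AlignedPair(six_cycle(), two_triangles())
        ensemble = generate_ensemble(pair, B=50, base_seed=6, swaps_per_edge=20)
        ps = [local_empirical_p(pair, ensemble, u) for u in pair.nodes]
        ps.append(global_empirical_p(pair, ensemble))
        assert all(1 / 51 <= p <= 1.0 for p in ps)


class TestMannWhitney:
    def test_printed_toy_case(self):
        assert mann_whitney_less([0, 0, 0], [1, 2, 3]) == pytest.approx(0.05)

    def test_identical_multisets_not_significant(self):
        sample = [1.0, 2.0, 3.0, 4.0]
        assert mann_whitney_less(sample, sample) >= 0.5

    def test_degenerate_input_returns_one_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            assert mann_whitney_less([2.0, 2.0], [2.0, 2.0, 2.0]) == 1.0
        assert any("identical" in r.message for r in caplog.records)

    @pytest.mark.parametrize("seed", range(10))
    def test_agrees_with_enumeration_oracle_small_samples(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 7))
        # small integer alphabet forces ties within and between samples
        x = rng.integers(0, 4, size=n).astype(float)
        y = rng.integers(0, 4, size=n).astype(float)
        assert mann_whitney_less(x, y) == pytest.approx(mwu_oracle(x, y), abs=1e-10)

    def test_large_sample_path_matches_scipy_asymptotic(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=300)
        y = rng.normal(0.2, size=300)
        from scipy.stats import mannwhitneyu

        expected = mannwhitneyu(x, y, alternative="less", method="asymptotic").pvalue
        assert mann_whitney_less(x, y) == pytest.approx(expected)

    def test_mwu_local_detects_preserved_structure(self):
        pair = AlignedPair(six_cycle(), six_cycle())
        members = [AlignedPair(two_triangles(), six_cycle()) for _ in range(30)]
        p = mwu_local(pair, handmade_ensemble(members))
        assert p < 0.01


class TestShortestPathAnalysis:
    def toy(self):
        hetero = graph_from_edges([], [])
        for d in ("D1", "D2", "D3"):
            hetero.add_node(d, type="disease")
        for p in ("p1", "p2", "p3"):
            hetero.add_node(p, type="protein")
        hetero.add_edges_from(
            [("D1", "p1"), ("D2", "p1"), ("D3", "p3"), ("p3", "p2"), ("p2", "p1")],
            weight=1.0,
        )
        reference = graph_from_edges(["D1", "D2", "D3"], [("D1", "D2")])
        return hetero, reference

    def test_x0_x1_split_on_toy_network(self):
        hetero, reference = self.toy()
        result = shortest_path_analysis(hetero, reference, "disease-disease")
        assert sorted(result.x1) == [2]
        assert sorted(result.x0) == [4, 4]
        assert result.n_unreachable == 0

    def test_unreachable_pairs_excluded_and_counted(self):
        hetero, reference = self.toy()
        hetero.add_node("D4", type="disease")
        reference.add_node("D4")
        result = shortest_path_analysis(hetero, reference, "disease-disease")
        assert result.n_unreachable == 3
        assert len(result.x0) + len(result.x1) == 3

    def test_reference_without_evaluated_edges_is_an_error(self):
        hetero, _ = self.toy()
        empty_ref = graph_from_edges(["D1", "D2", "D3"], [])
        with pytest.raises(ValueError, match="X1"):
            shortest_path_analysis(hetero, empty_ref, "disease-disease")

    def test_invariant_to_node_relabeling(self):
        hetero, reference = self.toy()
        mapping = {"D1": "Z9", "D2": "Z8", "D3": "Z7", "p1": "q1", "p2": "q2", "p3": "q3"}
        import networkx as nx

        hetero2 = nx.relabel_nodes(hetero, mapping)
        reference2 = nx.relabel_nodes(reference, mapping)
        r1 = shortest_path_analysis(hetero, reference, "disease-disease")
        r2 = shortest_path_analysis(hetero2, reference2, "disease-disease")
        assert sorted(r1.x0) == sorted(r2.x0)
        assert sorted(r1.x1) == sorted(r2.x1)
        assert r1.mwu_p == pytest.approx(r2.mwu_p)

    def test_unknown_pair_type_is_an_error(self):
        hetero, reference = self.toy()
        with pytest.raises(ValueError, match="pair type"):
            shortest_path_analysis(hetero, reference, "gene-gene")
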