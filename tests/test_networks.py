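"""Bipartite targeting networks, nulls, and over-targeting statistics."""

import math
from itertools import combinations

import numpy as np
import pytest

from mirweave.networks import (BipartiteNetwork, average_neighbors,
                               build_bipartite, mirna_overtargeting,
                               mrna_overtargeting, network_contrast_report,
                               proportion_gof_test, randomize_networks,
                               read_contrast_tsv, write_contrast_tsv)
from mirweave.universe import Edge, InteractionUniverse
from mirweave.hyper import hypergeom_upper_tail
from conftest import hypergeom_tail_comb, hypergeom_tail_enumerate


def _universe(pairs):
    return InteractionUniverse(edges=[Edge(m, g, "predicted", 4)
                                      for m, g in pairs])


class TestBipartite:
    def test_single_edge(self):
        net = build_bipartite(_universe([("m1", "g1")]), {"m1"}, {"g1"})
        assert len(net.edges) == 1 and net.n_nodes == 2
        assert average_neighbors(net) == 1.0

    def test_isolated_candidates_excluded(self):
        net = build_bipartite(_universe([("m1", "g1")]), {"m1", "m2"},
                              {"g1", "g2"})
        assert net.mirna_nodes == {"m1"} and net.gene_nodes == {"g1"}

    def test_complete_bipartite_enumeration(self):
        pairs = [(m, g) for m in ("m1", "m2") for g in ("g1", "g2", "g3")]
        net = build_bipartite(_universe(pairs), {"m1", "m2"},
                              {"g1", "g2", "g3"})
        assert len(net.edges) == 6
        assert average_neighbors(net) == pytest.approx(2.4)

    @pytest.mark.parametrize("a, b", [(1, 4), (2, 3), (5, 5), (1, 1)])
    def test_complete_bipartite_mean_degree_formula(self, a, b):
        pairs = [(f"m{i}", f"g{j}") for i in range(a) for j in range(b)]
        net = build_bipartite(_universe(pairs), {f"m{i}" for i in range(a)},
                              {f"g{j}" for j in range(b)})
        assert average_neighbors(net) == pytest.approx(2 * a * b / (a + b))

    def test_star_mean_degree(self):
        pairs = [("m1", f"g{j}") for j in range(4)]
        net = build_bipartite(_universe(pairs), {"m1"},
                              {f"g{j}" for j in range(4)})
        assert average_neighbors(net) == pytest.approx(1.6)

    def test_empty_network_rejected(self):
        with pytest.raises(ValueError):
            average_neighbors(BipartiteNetwork(set(), set(), set()))


class TestMirnaOvertargeting:
    def test_hand_enumeration_case(self):
        # N=10 targetable, K=5 targets, n=2 DE, k=2 -> 56/252
        genes = [f"g{i}" for i in range(10)]
        pairs = [("m1", g) for g in genes[:5]]
        pairs += [("mx", g) for g in genes]  # makes every gene targetable
        uni = _universe(pairs)
        table = mirna_overtargeting(uni, {"m1"}, de_set={"g0", "g1"},
                                    expressed=set(genes))
        assert table.loc["m1", "p"] == pytest.approx(56 / 252, abs=1e-12)

    def test_zero_overlap_p_one(self):
        genes = [f"g{i}" for i in range(8)]
        pairs = [("m1", g) for g in genes[:3]] + [("mx", g) for g in genes]
        table = mirna_overtargeting(_universe(pairs), {"m1"},
                                    de_set={"g6", "g7"}, expressed=set(genes))
        assert table.loc["m1", "p"] == 1.0

    def test_untargeted_mirna_excluded_but_reported(self):
        genes = ["g0", "g1"]
        pairs = [("m1", "g0"), ("m1", "g1")]
        table = mirna_overtargeting(_universe(pairs), {"m1", "m2"},
                                    de_set={"g0"}, expressed=set(genes))
        assert not table.loc["m2", "tested"]
        assert np.isnan(table.loc["m2", "p"])
        assert table.loc["m1", "tested"]

    def test_de_outside_expressed_rejected(self):
        with pytest.raises(ValueError):
            mirna_overtargeting(_universe([("m1", "g0")]), {"m1"},
                                de_set={"gX"}, expressed={"g0"})


class TestMrnaOvertargeting:
    def test_gene_targeted_by_all_de_mirnas(self):
        # 5-miRNA universe, 3 DE, gene targeted by exactly the 3 DE -> 1/10
        mirnas = [f"m{i}" for i in range(5)]
        pairs = [(m, "g1") for m in mirnas[:3]]
        pairs += [(m, "gpad") for m in mirnas]  # all 5 in the universe
        table = mrna_overtargeting(_universe(pairs), set(mirnas[:3]),
                                   expressed_mirnas=set(mirnas),
                                   gene_set={"g1", "gpad"})
        assert table.loc["g1", "p"] == pytest.approx(1 / 10, abs=1e-12)

    def test_no_de_mirnas_p_one(self):
        mirnas = [f"m{i}" for i in range(4)]
        pairs = [(m, "g1") for m in mirnas[:2]] + [(m, "gp") for m in mirnas]
        table = mrna_overtargeting(_universe(pairs), set(),
                                   expressed_mirnas=set(mirnas),
                                   gene_set={"g1"})
        assert table.loc["g1", "p"] == 1.0

    def test_singly_targeted_gene_excluded(self):
        pairs = [("m1", "g1"), ("m1", "g2"), ("m2", "g2")]
        table = mrna_overtargeting(_universe(pairs), {"m1"},
                                   expressed_mirnas={"m1", "m2"},
                                   gene_set={"g1", "g2"})
        assert not table.loc["g1", "tested"]
        assert table.loc["g2", "tested"]


class TestHypergeomKernel:
    def test_matches_closed_form_on_all_small_instances(self):
        for N in range(1, 13):
            for K in range(N + 1):
                for n in range(N + 1):
                    for k in range(min(K, n) + 1):
                        assert hypergeom_upper_tail(k, N, K, n) == pytest.approx(
                            hypergeom_tail_comb(k, N, K, n), abs=1e-12)

    def test_matches_subset_enumeration(self):
        for (k, N, K, n) in [(2, 10, 2, 5), (1, 8, 3, 4), (3, 9, 4, 5),
                             (2, 7, 5, 3)]:
            assert hypergeom_upper_tail(k, N, K, n) == pytest.approx(
                hypergeom_tail_enumerate(k, N, K, n), abs=1e-12)

    def test_monotone_nonincreasing_in_k(self):
        N, K, n = 40, 15, 12
        ps = [hypergeom_upper_tail(k, N, K, n) for k in range(min(K, n) + 1)]
        assert all(a >= b - 1e-15 for a, b in zip(ps, ps[1:]))


class TestRandomizeNetworks:
    def _toy_universe(self):
        genes = [f"g{i}" for i in range(6)]
        rng = np.random.default_rng(17)
        pairs = [(f"m{i}", g) for i in range(3) for g in genes
                 if rng.random() < 0.6]
        return _universe(pairs), set(genes)

    def test_degenerate_sampling_returns_observed(self):
        uni, genes = self._toy_universe()
        mirnas = {"m0", "m1", "m2"}
        null = randomize_networks(uni, mirnas, genes, gene_set_size=len(genes),
                                  R=5, seed=1)
        net = build_bipartite(uni, mirnas, genes)
        assert np.allclose(null.mean_degrees, average_neighbors(net))

    def test_monte_carlo_matches_exhaustive_average(self):
        uni, genes = self._toy_universe()
        mirnas = {"m0", "m1", "m2"}
        ordered = sorted(genes)
        exact = []
        for subset in combinations(ordered, 3):
            net = build_bipartite(uni, mirnas, set(subset))
            exact.append(average_neighbors(net) if net.edges else np.nan)
        exact = np.array(exact, dtype=float)
        null = randomize_networks(uni, mirnas, genes, gene_set_size=3,
                                  R=10_000, seed=2)
        se = np.nanstd(exact) / math.sqrt(null.R)
        assert abs(null.mean_degree - np.nanmean(exact)) < 3 * se + 1e-9

    def test_same_seed_identical(self):
        uni, genes = self._toy_universe()
        a = randomize_networks(uni, {"m0", "m1"}, genes, 3, R=50, seed=9)
        b = randomize_networks(uni, {"m0", "m1"}, genes, 3, R=50, seed=9)
        np.testing.assert_array_equal(a.mean_degrees, b.mean_degrees)
        np.testing.assert_array_equal(a.overtarget_proportions,
                                      b.overtarget_proportions)


class TestProportionGof:
    def test_printed_comparisons(self):
        _, p_pos = proportion_gof_test(38, 48, 0.49)
        assert p_pos < 1e-4
        _, p_neg = proportion_gof_test(10, 41, 0.49)
        assert p_neg == pytest.approx(0.0016, rel=0.10)

    def test_exact_expectation_gives_null(self):
        chi2, p = proportion_gof_test(20, 40, 0.5)
        assert chi2 == pytest.approx(0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            proportion_gof_test(1, 0, 0.5)
        with pytest.raises(ValueError):
            proportion_gof_test(5, 4, 0.5)


class TestContrastReport:
    def test_round_trip_and_flags(self, small_dataset, tmp_path):
        mirna, mrna, traits, universe, truth = small_dataset
        up_m = {m for m, l in truth.mirna_de_labels.items() if l == "up"}
        up_g = {g for g, l in truth.gene_de_labels.items() if l == "up"}
        down_g = {g for g, l in truth.gene_de_labels.items() if l == "down"}
        expressed = set(mrna.feature_ids)
        pos = build_bipartite(universe, up_m, up_g, "positive")
        neg = build_bipartite(universe, up_m, down_g, "negative")
        ot_pos = mirna_overtargeting(universe, up_m, up_g, expressed)
        ot_neg = mirna_overtargeting(universe, up_m, down_g, expressed)
        null_pos = randomize_networks(universe, up_m, expressed, len(up_g),
                                      R=60, seed=4)
        null_neg = randomize_networks(universe, up_m, expressed, len(down_g),
                                      R=60, seed=5)
        report = network_contrast_report(pos, neg, null_pos, null_neg,
                                         ot_pos, ot_neg)
        path = write_contrast_tsv(report, tmp_path / "contrast.tsv")
        back = read_contrast_tsv(path)
        assert list(back.index) == list(report.index)
        np.testing.assert_allclose(back["mean_degree"], report["mean_degree"],
                                   rtol=1e-9)
        # the generator plants up-up enrichment: positive network enriched
        assert report.loc["positive", "connectivity"] == "enriched"
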