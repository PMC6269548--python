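"""KO assignment, profile statistics, rank tests, FDR and enrichment."""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd
import pytest

from straintrace.functional import (DifferentialResult, GeneHit, KOTable,
                                    adjust_fdr, aggregate_ko_counts,
                                    assign_best_ko, cumulative_pathway_abundance,
                                    differential_kos, diversity_indices,
                                    genome_function_enrichment, gram_fraction,
                                    jensen_shannon, pathway_enrichment,
                                    spearman_profile_correlation, wilcoxon_groups)

from conftest import fisher_two_sided_enumeration, hypergeom_upper_tail_enumeration


class TestBestKo:
    def test_highest_bit_score_wins_above_threshold(self):
        # threshold log2(1024) = 10 bits
        hit = GeneHit("g", "S", {"K00001": 12.0, "K00002": 11.0}, 5)
        assert assign_best_ko(hit, 1024) == "K00001"

    def test_score_below_threshold_unassigned(self):
        hit = GeneHit("g", "S", {"K00001": 9.5}, 5)
        assert assign_best_ko(hit, 1024) is None

    def test_threshold_is_strict(self):
        hit = GeneHit("g", "S", {"K00001": 10.0}, 1024)
        assert assign_best_ko(hit, 1024) is None

    def test_no_candidates(self):
        assert assign_best_ko(GeneHit("g", "S", {}, 5), 10) is None

    def test_score_tie_breaks_to_smallest_ko(self):
        hit = GeneHit("g", "S", {"K00009": 50.0, "K00002": 50.0}, 5)
        assert assign_best_ko(hit, 4) == "K00002"


class TestAggregation:
    def test_read_counts_sum_per_ko(self):
        hits = [GeneHit("g1", "S", {"K1": 30.0}, 10),
                GeneHit("g2", "S", {"K1": 30.0}, 5)]
        table = aggregate_ko_counts({"g1": "K1", "g2": "K1"}, hits)
        assert table.counts.loc["S", "K1"] == 15

    def test_unassigned_genes_excluded_and_sample_flagged(self, caplog):
        hits = [GeneHit("g1", "S", {"K1": 2.0}, 10)]
        table = aggregate_ko_counts({"g1": None}, hits)
        rel = table.relative()
        assert rel.loc["S"].isna().all()

    def test_gene_order_irrelevant(self):
        hits = [GeneHit("g1", "S", {"K1": 30.0}, 10),
                GeneHit("g2", "S", {"K2": 30.0}, 5)]
        t1 = aggregate_ko_counts({"g1": "K1", "g2": "K2"}, hits)
        t2 = aggregate_ko_counts({"g1": "K1", "g2": "K2"}, hits[::-1])
        pd.testing.assert_frame_equal(t1.counts, t2.counts)


class TestJensenShannon:
    def test_identical_profiles(self):
        assert jensen_shannon({"a": 0.5, "b": 0.5}, {"a": 0.5, "b": 0.5}) == 0.0

    def test_disjoint_supports_reach_one(self):
        assert jensen_shannon({"a": 1.0}, {"b": 1.0}) == pytest.approx(1.0)

    def test_hand_computed_value(self):
        # p=(1,0), q=(0.5,0.5) against mixture (0.75,0.25) -> 0.3113 bits
        assert jensen_shannon([1.0, 0.0], [0.5, 0.5]) == pytest.approx(0.311278, abs=1e-4)

    def test_unnormalised_input_rejected(self):
        with pytest.raises(ValueError, match="normalised"):
            jensen_shannon([0.5, 0.2], [0.5, 0.5])

    def test_symmetry_and_bounds_on_random_profiles(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            p = rng.dirichlet(np.ones(6))
            q = rng.dirichlet(np.ones(6))
            d1 = jensen_shannon(p, q)
            d2 = jensen_shannon(q, p)
            assert d1 == pytest.approx(d2)
            assert 0.0 <= d1 <= 1.0 + 1e-12


class TestSpearman:
    def test_identical_profiles(self):
        assert spearman_profile_correlation([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)

    def test_hand_computed_case(self):
        # x=(1,2,3), y=(3,1,2): sum d^2 = 6 -> rho = -0.5
        assert spearman_profile_correlation([1, 2, 3], [3, 1, 2]) == pytest.approx(-0.5)

    def test_reversed_ranks(self):
        assert spearman_profile_correlation([1, 2, 3, 4], [4, 3, 2, 1]) == pytest.approx(-1.0)

    def test_zero_variance_undefined(self):
        assert math.isnan(spearman_profile_correlation([1, 1, 1], [1, 2, 3]))


class TestWilcoxon:
    def test_exact_two_versus_two(self):
        # {1,2} vs {3,4}: 2 of 6 rank assignments as extreme -> p = 1/3
        assert wilcoxon_groups([1, 2], [3, 4]) == pytest.approx(1 / 3)

    def test_identical_multisets_give_p_one(self):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            assert wilcoxon_groups([1.0, 1.0], [1.0, 1.0]) == 1.0

    def test_extreme_ten_versus_ten(self):
        p = wilcoxon_groups(list(range(1, 11)), list(range(11, 21)))
        assert p == pytest.approx(2 / 184_756)

    def test_paired_signed_rank_mode(self):
        p = wilcoxon_groups([1, 2, 3, 4, 5, 6], [2, 3, 4, 5, 6, 7], paired=True)
        assert 0 < p < 0.1

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_groups([], [1.0])


class TestFdr:
    def test_hand_case_collapses_to_common_value(self):
        adjusted = adjust_fdr([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(adjusted, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert adjust_fdr([0.2])[0] == pytest.approx(0.2)

    def test_all_ones(self):
        assert np.allclose(adjust_fdr([1.0, 1.0, 1.0]), 1.0)

    def test_order_preserved(self):
        p = [0.04, 0.01, 0.03, 0.02]
        adjusted = adjust_fdr(p)
        assert np.allclose(sorted(adjusted), adjust_fdr(sorted(p)))


class TestDifferentialKos:
    @staticmethod
    def _table(values_by_sample):
        counts = pd.DataFrame(values_by_sample).T
        counts.columns = [f"K{i}" for i in range(counts.shape[1])]
        return KOTable(counts)

    def test_opposite_directions_are_not_flagged(self):
        # K0 is up in VD vs CSD but down vs CSD_SGA: directionality rule vetoes
        samples, groups, days = {}, {}, {}
        rng = np.random.default_rng(0)
        for i in range(6):
            samples[f"v{i}"] = [100 + i, 50 + rng.integers(5)]
            groups[f"v{i}"] = "VD"
            days[f"v{i}"] = 3 if i % 2 else 5
        for i in range(6):
            samples[f"c{i}"] = [10 + i, 50 + rng.integers(5)]
            groups[f"c{i}"] = "CSD"
            days[f"c{i}"] = 3 if i % 2 else 5
        for i in range(6):
            samples[f"s{i}"] = [500 + i, 50 + rng.integers(5)]
            groups[f"s{i}"] = "CSD_SGA"
            days[f"s{i}"] = 3 if i % 2 else 5
        res = differential_kos(self._table(samples), groups, days)
        k0 = next(r for r in res if r.ko == "K0")
        assert k0.directions["VD_vs_CSD"] == 1
        assert k0.directions["VD_vs_CSD_SGA"] == -1
        assert not k0.da

    def test_consistent_strong_contrast_is_flagged(self):
        samples, groups, days = {}, {}, {}
        for i in range(6):
            samples[f"v{i}"] = [100 + i, 50]
            groups[f"v{i}"], days[f"v{i}"] = "VD", 3
        for i in range(6):
            samples[f"c{i}"] = [i, 50]
            groups[f"c{i}"], days[f"c{i}"] = "CSD", 3
        for i in range(6):
            samples[f"s{i}"] = [10 + i, 50]
            groups[f"s{i}"], days[f"s{i}"] = "CSD_SGA", 3
        res = differential_kos(self._table(samples), groups, days)
        k0 = next(r for r in res if r.ko == "K0")
        assert k0.da and all(d == 1 for d in k0.directions.values())

    def test_missing_group_falls_back_to_remaining_comparison(self):
        samples, groups, days = {}, {}, {}
        for i in range(6):
            samples[f"v{i}"] = [100 + i, 50]
            groups[f"v{i}"], days[f"v{i}"] = "VD", 3
        for i in range(6):
            samples[f"c{i}"] = [i, 50]
            groups[f"c{i}"], days[f"c{i}"] = "CSD", 3
        res = differential_kos(self._table(samples), groups, days)
        k0 = next(r for r in res if r.ko == "K0")
        assert list(k0.q_values) == ["VD_vs_CSD"]
        assert k0.da


class TestEnrichment:
    def test_hand_computed_hypergeometric_case(self):
        # universe 10, pathway 4, 5 draws, overlap 4 -> C(4,4)C(6,1)/C(10,5)
        universe = {f"K{i}" for i in range(10)}
        pathway = {"K0", "K1", "K2", "K3"}
        da = {"K0", "K1", "K2", "K3", "K4"}
        res = pathway_enrichment(da, universe, {"pw": pathway})
        assert res.iloc[0]["p"] == pytest.approx(6 / 252)

    def test_no_draws_gives_p_one(self):
        universe = {f"K{i}" for i in range(10)}
        res = pathway_enrichment(set(), universe, {"pw": {"K0"}})
        assert res.iloc[0]["p"] == 1.0

    def test_pathway_equals_universe_gives_p_one(self):
        universe = {f"K{i}" for i in range(8)}
        res = pathway_enrichment({"K0", "K1"}, universe, {"pw": set(universe)})
        assert res.iloc[0]["p"] == pytest.approx(1.0)

    def test_empty_pathway_flagged(self):
        universe = {"K0", "K1"}
        res = pathway_enrichment({"K0"}, universe, {"pw": {"K9"}})
        assert res.iloc[0]["p"] == 1.0 and bool(res.iloc[0]["empty"])

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(9)
        for _ in range(40):
            M = int(rng.integers(4, 41))
            K = int(rng.integers(1, M + 1))
            n = int(rng.integers(1, M + 1))
            universe = {f"K{i}" for i in range(M)}
            pathway = set(list(universe)[:K])
            da = set(rng.choice(sorted(universe), size=n, replace=False))
            overlap = len(pathway & da)
            res = pathway_enrichment(da, universe, {"pw": pathway})
            expected = hypergeom_upper_tail_enumeration(overlap, M, K, n)
            assert res.iloc[0]["p"] == pytest.approx(expected, abs=1e-12)


class TestFisher:
    def test_sample_odds_ratio(self):
        universe = {f"K{i}" for i in range(25)}
        ordered = sorted(universe)
        bin_kos = set(ordered[:15])          # a=10, b=5
        da = set(ordered[:10]) | set(ordered[15:17])  # c=2, d=8
        res = genome_function_enrichment(bin_kos, da, universe)
        assert res.odds_ratio == pytest.approx(8.0)
        assert res.table == (10, 5, 2, 8)

    def test_independent_table(self):
        universe = {f"K{i}" for i in range(20)}
        ordered = sorted(universe)
        bin_kos = set(ordered[:10])
        da = set(ordered[5:15])
        res = genome_function_enrichment(bin_kos, da, universe)
        assert res.odds_ratio == pytest.approx(1.0)
        assert res.p_value == pytest.approx(1.0)

    def test_degenerate_margin_flagged(self):
        universe = {"K0", "K1"}
        res = genome_function_enrichment(set(), {"K0"}, universe)
        assert res.degenerate and res.p_value == 1.0

    def test_zero_cell_uses_haldane_correction(self):
        universe = {f"K{i}" for i in range(10)}
        ordered = sorted(universe)
        res = genome_function_enrichment(set(ordered[:5]), set(ordered[:5]), universe)
        assert res.haldane and np.isfinite(res.odds_ratio)

    def test_p_matches_enumeration_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(40):
            M = int(rng.integers(4, 41))
            universe = {f"K{i}" for i in range(M)}
            ordered = sorted(universe)
            nb = int(rng.integers(1, M))
            nd = int(rng.integers(1, M))
            bin_kos = set(rng.choice(ordered, nb, replace=False))
            da = set(rng.choice(ordered, nd, replace=False))
            a = len(bin_kos & da)
            b = len(bin_kos - da)
            c = len(da - bin_kos)
            d = M - a - b - c
            if min(a + b, c + d, a + c, b + d) == 0:
                continue
            res = genome_function_enrichment(bin_kos, da, universe)
            expected = fisher_two_sided_enumeration(a, b, c, d)
            assert res.p_value == pytest.approx(expected, abs=1e-12)


class TestProfiles:
    def test_cumulative_abundance_sums_pathway_members(self):
        profile = {"K1": 0.2, "K2": 0.3, "K3": 0.5}
        assert cumulative_pathway_abundance(profile, {"K1", "K3"}) == pytest.approx(0.7)
        assert cumulative_pathway_abundance(profile, set()) == 0.0
        assert cumulative_pathway_abundance(profile, set(profile)) == pytest.approx(1.0)

    def test_gram_fraction_by_label(self):
        table = {"Bacteroides": "negative", "Staphylococcus": "positive"}
        out = gram_fraction({"Bacteroides": 0.6, "Staphylococcus": 0.4}, table)
        assert out == {"negative": pytest.approx(0.6),
                       "positive": pytest.approx(0.4), "unknown": 0.0}

    def test_unlabelled_genus_counts_as_unknown(self):
        out = gram_fraction({"Mysterium": 0.1, "Bacteroides": 0.9},
                            {"Bacteroides": "negative"})
        assert out["unknown"] == pytest.approx(0.1)
        assert out["negative"] == pytest.approx(0.9)

    def test_diversity_of_even_pair(self):
        richness, shannon, pielou = diversity_indices([0.5, 0.5])
        assert richness == 2
        assert shannon == pytest.approx(math.log(2))
        assert pielou == pytest.approx(1.0)

    def test_single_taxon_has_undefined_evenness(self):
        richness, shannon, pielou = diversity_indices({"x": 1.0})
        assert richness == 1 and shannon == 0.0 and math.isnan(pielou)

    def test_uniform_profiles_are_maximally_even(self):
        for k in (2, 5, 9):
            _, _, pielou = diversity_indices([1 / k] * k)
            assert pielou == pytest.approx(1.0)

    def test_all_zero_profile_undefined(self):
        assert all(math.isnan(v) for v in diversity_indices([0.0, 0.0]))
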