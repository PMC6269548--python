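"""SNV filters, qualification gates, downsampling, pi and F_ST estimators."""

from __future__ import annotations

import numpy as np
import pytest

from straintrace.popgen import (CoverageSummary, EmptyIntersectionError, Pileup,
                                call_snvs, compute_fst, compute_pi,
                                downsample_to_median, filter_pileup,
                                intersect_loci, qualify_genome_sample)

from conftest import pi_enumeration


def _pileup(columns, genome="G", sample="S", length=None):
    """Build a pileup from a dict {position: (nA, nC, nG, nT)}."""
    length = length or (max(columns) + 1 if columns else 1)
    counts = np.zeros((length, 4), dtype=np.int64)
    for pos, row in columns.items():
        counts[pos] = row
    return Pileup(genome, sample, counts)


class TestQualification:
    @pytest.mark.parametrize("median,breadth,completeness,included,reason", [
        (19, 0.50, 0.80, False, "coverage"),
        (25, 0.39, 0.80, False, "breadth"),
        (25, 0.50, 0.70, True, None),
        (20, 0.40, 0.66, True, None),      # inclusive coverage/breadth bounds
        (25, 0.50, 0.65, False, "completeness"),  # completeness is strict
    ])
    def test_gate_boundaries(self, median, breadth, completeness, included, reason):
        summary = CoverageSummary("G", "S", median, breadth, completeness)
        ok, reasons = qualify_genome_sample(summary)
        assert ok is included
        if reason:
            assert reason in reasons

    def test_all_failing_reasons_listed(self):
        ok, reasons = qualify_genome_sample(CoverageSummary("G", "S", 5, 0.1, 0.2))
        assert not ok
        assert set(reasons) == {"coverage", "breadth", "completeness"}


class TestDownsampling:
    def test_at_or_below_target_is_identity(self):
        pile = _pileup({i: (20, 0, 0, 0) for i in range(50)})
        assert downsample_to_median(pile, 20, seed=0) is pile

    def test_thinned_median_concentrates_at_target(self):
        # median 40 thinned to 20: the mean realized median over many seeds
        # stays within 20 +/- 1 (binomial thinning expectation)
        pile = _pileup({i: (40, 0, 0, 0) for i in range(500)})
        medians = [downsample_to_median(pile, 20, seed=s).median_depth()
                   for s in range(1000)]
        assert abs(np.mean(medians) - 20) < 1

    def test_depth_one_column_dropped_half_the_time(self):
        pile = _pileup({0: (1, 0, 0, 0), 1: (2, 0, 0, 0), 2: (2, 0, 0, 0)})
        # median 2, target 1 -> p = 0.5 per read
        dropped = sum(downsample_to_median(pile, 1, seed=s).depth[0] == 0
                      for s in range(2000))
        assert 0.45 < dropped / 2000 < 0.55

    def test_invalid_target_rejected(self):
        with pytest.raises(ValueError, match="target"):
            downsample_to_median(_pileup({0: (5, 0, 0, 0)}), 0)


class TestSnvFilters:
    def test_support_three_reads_rejected(self):
        calls = call_snvs(_pileup({0: (96, 3, 0, 0)}))
        assert calls == []

    def test_frequency_below_one_percent_rejected(self):
        calls = call_snvs(_pileup({0: (995, 5, 0, 0)}))
        assert calls == []

    def test_both_inclusive_boundaries_retained(self):
        calls = call_snvs(_pileup({0: (96, 4, 0, 0)}))
        assert len(calls) == 1
        assert calls[0].alleles["C"] == (4, pytest.approx(0.04))

    def test_filter_pileup_zeroes_subthreshold_minor_alleles(self):
        pile = _pileup({0: (96, 3, 0, 0), 1: (90, 10, 0, 0)})
        filtered = filter_pileup(pile)
        assert filtered.counts[0].tolist() == [96, 0, 0, 0]
        assert filtered.counts[1].tolist() == [90, 10, 0, 0]


class TestLocusIntersection:
    def test_overlapping_windows(self):
        a = _pileup({i: (5, 0, 0, 0) for i in range(0, 100)}, length=150)
        b = _pileup({i: (5, 0, 0, 0) for i in range(50, 150)}, length=150)
        loci = intersect_loci([a, b])
        assert loci.tolist() == list(range(50, 100))

    def test_identical_coverage_keeps_all(self):
        a = _pileup({i: (5, 0, 0, 0) for i in range(30)})
        b = _pileup({i: (2, 1, 0, 0) for i in range(30)})
        assert intersect_loci([a, b]).size == 30

    def test_disjoint_coverage_is_an_error(self):
        a = _pileup({i: (5, 0, 0, 0) for i in range(10)}, length=30)
        b = _pileup({i: (5, 0, 0, 0) for i in range(20, 30)}, length=30)
        with pytest.raises(EmptyIntersectionError):
            intersect_loci([a, b])


class TestPi:
    def test_plugin_half_half_column(self):
        # {A:2, C:2}: 8 of 16 ordered with-replacement pairs discordant
        pile = _pileup({0: (2, 2, 0, 0)})
        assert compute_pi(pile, [0], "plugin") == pytest.approx(0.5)

    def test_unbiased_half_half_column(self):
        # without replacement: 8 of 12 ordered pairs discordant
        pile = _pileup({0: (2, 2, 0, 0)})
        assert compute_pi(pile, [0], "unbiased") == pytest.approx(2 / 3)

    def test_mean_over_loci_includes_monomorphic(self):
        pile = _pileup({0: (3, 0, 1, 0), 1: (4, 0, 0, 0)})
        assert compute_pi(pile, [0, 1], "plugin") == pytest.approx(0.1875)

    def test_matches_enumeration_oracle_on_random_columns(self):
        rng = np.random.default_rng(17)
        for _ in range(60):
            n_loci = int(rng.integers(1, 8))
            cols = {}
            for pos in range(n_loci):
                counts = rng.multinomial(int(rng.integers(2, 20)),
                                         rng.dirichlet(np.ones(4) * 0.6))
                cols[pos] = tuple(int(x) for x in counts)
            pile = _pileup(cols)
            loci = list(range(n_loci))
            for mode in ("plugin", "unbiased"):
                expected = np.mean([pi_enumeration(np.array(cols[p]), mode)
                                    for p in loci
                                    if mode == "plugin" or sum(cols[p]) >= 2])
                import warnings as _w
                with _w.catch_warnings():
                    _w.simplefilter("ignore")
                    got = compute_pi(pile, loci, mode)
                assert got == pytest.approx(expected, abs=1e-12)

    def test_invariant_to_allele_relabelling(self):
        pile1 = _pileup({0: (6, 2, 0, 0)})
        pile2 = _pileup({0: (0, 0, 2, 6)})
        assert compute_pi(pile1, [0]) == compute_pi(pile2, [0])

    def test_adding_monomorphic_locus_cannot_increase_pi(self):
        poly = _pileup({0: (5, 5, 0, 0), 1: (9, 0, 0, 0)})
        assert compute_pi(poly, [0, 1]) <= compute_pi(poly, [0])


class TestFst:
    def test_identical_samples_give_zero_plugin(self):
        a = _pileup({0: (3, 1, 0, 0), 1: (5, 0, 0, 0)}, sample="S1")
        b = _pileup({0: (3, 1, 0, 0), 1: (5, 0, 0, 0)}, sample="S2")
        assert compute_fst(a, b, [0, 1], "plugin") == pytest.approx(0.0)

    def test_fixed_difference_gives_one(self):
        a = _pileup({0: (10, 0, 0, 0)}, sample="S1")
        b = _pileup({0: (0, 10, 0, 0)}, sample="S2")
        assert compute_fst(a, b, [0]) == pytest.approx(1.0)

    def test_worked_three_one_example(self):
        # {A:3,C:1} vs {A:1,C:3}: intra 0.375 each, between 0.625 -> 0.4
        a = _pileup({0: (3, 1, 0, 0)}, sample="S1")
        b = _pileup({0: (1, 3, 0, 0)}, sample="S2")
        assert compute_fst(a, b, [0]) == pytest.approx(0.4)

    def test_symmetry(self):
        a = _pileup({0: (7, 3, 0, 0), 1: (5, 5, 0, 0)}, sample="S1")
        b = _pileup({0: (2, 8, 0, 0), 1: (9, 1, 0, 0)}, sample="S2")
        assert compute_fst(a, b, [0, 1]) == pytest.approx(compute_fst(b, a, [0, 1]))

    def test_monotone_along_frequency_divergence_path(self):
        values = []
        for shift in range(0, 5):
            a = _pileup({0: (10 + shift, 10 - shift, 0, 0)}, sample="S1")
            b = _pileup({0: (10 - shift, 10 + shift, 0, 0)}, sample="S2")
            values.append(compute_fst(a, b, [0]))
        assert all(x < y for x, y in zip(values, values[1:]))

    def test_no_between_diversity_is_undefined(self):
        a = _pileup({0: (5, 0, 0, 0)}, sample="S1")
        b = _pileup({0: (7, 0, 0, 0)}, sample="S2")
        assert np.isnan(compute_fst(a, b, [0]))

    def test_different_genomes_rejected(self):
        a = _pileup({0: (5, 0, 0, 0)}, genome="G1")
        b = _pileup({0: (5, 0, 0, 0)}, genome="G2")
        with pytest.raises(ValueError, match="same genome"):
            compute_fst(a, b, [0])


class TestParameterRecovery:
    def test_estimated_pi_tracks_truth_at_depth_100(self):
        # plugin pi at depth 100 over 1,000 loci recovers the planted value
        # within +/- (0.1 * true + 0.002)
        from straintrace.simulate import CohortConfig, generate_cohort

        cfg = CohortConfig(n_pairs_per_group={"VD": 2, "CSD": 1, "CSD_SGA": 1},
                           genome_length=10_000, n_kos=200,
                           poly_site_fraction=0.1,
                           depth_mean={"faecal": 400.0, "vaginal": 100.0,
                                       "cell_culture": 100.0},
                           seed=23)
        cohort = generate_cohort(cfg)
        checked = 0
        for (gid, sid), pile in cohort.pileups.items():
            if pile.median_depth() < 100:
                continue
            loci = pile.covered_positions
            est = compute_pi(pile, loci, "plugin")
            true = cohort.truth.true_pi[(gid, sid)]
            assert abs(est - true) < 0.1 * true + 0.002
            checked += 1
        assert checked >= 5
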