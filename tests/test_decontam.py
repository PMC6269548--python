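"""Artefact removal: k-mer screen, composition embedding, joint binning, flagging."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import silhouette_score

from straintrace.decontam import (Contig, ContigBin, apply_decontamination,
                                  canonical_kmers, control_kmer_index,
                                  decontaminate_sample, embed_contigs,
                                  flag_artefact_bins, joint_bin,
                                  screen_against_control)
from straintrace.simulate.sequences import decode_sequence, random_genome


def _random_contig(cid, sample, length, gc, seed):
    rng = np.random.default_rng(seed)
    return Contig(cid, sample, decode_sequence(random_genome(length, gc, rng)))


def _naive_canonical_kmers(seq: str, k: int) -> set[str]:
    comp = str.maketrans("ACGT", "TGCA")
    out = set()
    for i in range(len(seq) - k + 1):
        kmer = seq[i:i + k]
        rc = kmer.translate(comp)[::-1]
        out.add(min(kmer, rc))
    return out


def _decode_kmer(code: int, k: int) -> str:
    bases = []
    for _ in range(k):
        bases.append("ACGT"[code % 4])
        code //= 4
    return "".join(reversed(bases))


class TestKmerScreen:
    def test_canonical_kmers_match_string_oracle(self):
        rng = np.random.default_rng(5)
        seq = decode_sequence(random_genome(300, 0.5, rng))
        for k in (11, 15):
            fast = {_decode_kmer(int(c), k) for c in canonical_kmers(seq, k)}
            assert fast == _naive_canonical_kmers(seq, k)

    def test_contig_identical_to_control_is_removed(self):
        control = [_random_contig("ctl1", "CTRL", 2000, 0.6, 1)]
        sample = [Contig("s1", "S", control[0].sequence),
                  _random_contig("s2", "S", 2000, 0.4, 2)]
        removed, kept = screen_against_control(sample, control)
        assert removed == {"s1"} and kept == {"s2"}

    def test_contig_sharing_no_kmers_is_kept(self):
        control = [_random_contig("ctl1", "CTRL", 2000, 0.6, 3)]
        sample = [_random_contig("s1", "S", 2000, 0.4, 4)]
        removed, kept = screen_against_control(sample, control)
        assert removed == set() and kept == {"s1"}

    def test_half_copied_contig_stays_below_default_containment(self):
        # first half copies the control, second half is random: containment
        # ~0.5 < 0.9, so the contig survives the screen
        control = [_random_contig("ctl1", "CTRL", 2000, 0.6, 5)]
        tail = _random_contig("x", "S", 1000, 0.4, 6).sequence
        sample = [Contig("s1", "S", control[0].sequence[:1000] + tail)]
        removed, kept = screen_against_control(sample, control)
        assert kept == {"s1"}

    def test_short_contig_kept_with_warning(self, caplog):
        control = [_random_contig("ctl1", "CTRL", 2000, 0.6, 7)]
        sample = [Contig("s1", "S", "ACGTACGTAC")]
        removed, kept = screen_against_control(sample, control, k=31)
        assert kept == {"s1"}

    def test_small_k_rejected(self):
        control = [_random_contig("c", "CTRL", 100, 0.5, 8)]
        with pytest.raises(ValueError, match="k must be"):
            screen_against_control(control, control, k=5)

    def test_screen_monotone_in_control_set(self):
        # removal is monotone: adding control contigs never un-removes
        rng_ids = range(10)
        control_a = [_random_contig(f"c{i}", "CTRL", 1500, 0.6, 100 + i)
                     for i in rng_ids]
        sample = [Contig("s0", "S", control_a[0].sequence)] + \
                 [_random_contig(f"s{i}", "S", 1500, 0.45, 200 + i)
                  for i in range(1, 6)]
        removed_small, _ = screen_against_control(sample, control_a[:3])
        removed_big, _ = screen_against_control(sample, control_a)
        assert removed_small <= removed_big


class TestEmbedding:
    def test_identical_sequences_identical_coordinates(self):
        base = _random_contig("a", "S", 3000, 0.5, 9)
        contigs = [base, Contig("b", "S", base.sequence),
                   _random_contig("c", "S", 3000, 0.3, 10)]
        emb = embed_contigs(contigs)
        assert np.allclose(emb.loc["a"].values, emb.loc["b"].values)

    def test_default_embedding_deterministic(self):
        contigs = [_random_contig(f"c{i}", "S", 2000, 0.4 + 0.02 * i, i)
                   for i in range(8)]
        emb1 = embed_contigs(contigs)
        emb2 = embed_contigs(contigs)
        pd.testing.assert_frame_equal(emb1, emb2)

    def test_gc_groups_separate_in_embedding(self):
        # contigs from two genomes at GC 0.35 vs 0.65 form silhouette > 0.5
        rng = np.random.default_rng(11)
        g1 = random_genome(60_000, 0.35, rng)
        g2 = random_genome(60_000, 0.65, rng)
        contigs, labels = [], []
        for name, genome, lab in (("lo", g1, 0), ("hi", g2, 1)):
            for i in range(12):
                seq = decode_sequence(genome[i * 5000:(i + 1) * 5000])
                contigs.append(Contig(f"{name}{i}", "S", seq))
                labels.append(lab)
        emb = embed_contigs(contigs)
        assert silhouette_score(emb.values, labels) > 0.5

    def test_too_few_contigs_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            embed_contigs([_random_contig("a", "S", 1000, 0.5, 1)])


class TestJointBin:
    @staticmethod
    def _embedding(points, ids):
        return pd.DataFrame(points, index=ids, columns=["x", "y"])

    def test_two_separated_clouds_give_two_bins(self):
        rng = np.random.default_rng(12)
        cloud1 = rng.normal(0, 0.05, size=(10, 2))
        cloud2 = rng.normal(10, 0.05, size=(10, 2))
        ids = [f"c{i}" for i in range(20)]
        contigs = [Contig(i, "S", "ACGT" * 100) for i in ids]
        emb = self._embedding(np.vstack([cloud1, cloud2]), ids)
        bins, noise = joint_bin(emb, contigs, "CTRL", eps=1.0, min_points=5)
        assert len(bins) == 2 and not noise

    def test_far_point_is_noise(self):
        pts = np.vstack([np.random.default_rng(0).normal(0, 0.01, (6, 2)),
                         [[50.0, 50.0]]])
        ids = [f"c{i}" for i in range(7)]
        contigs = [Contig(i, "S", "ACGT" * 100) for i in ids]
        bins, noise = joint_bin(self._embedding(pts, ids), contigs, "CTRL",
                                eps=1.0, min_points=5)
        assert "c6" in noise

    def test_coincident_points_form_one_bin(self):
        pts = np.zeros((8, 2))
        ids = [f"c{i}" for i in range(8)]
        contigs = [Contig(i, "S", "ACGT" * 50) for i in ids]
        bins, noise = joint_bin(self._embedding(pts, ids), contigs, "CTRL",
                                eps=0.5, min_points=5)
        assert len(bins) == 1 and set(bins[0].members) == set(ids)

    def test_nonpositive_eps_rejected(self):
        ids = ["a", "b", "c"]
        contigs = [Contig(i, "S", "ACGT" * 50) for i in ids]
        with pytest.raises(ValueError, match="eps"):
            joint_bin(self._embedding(np.zeros((3, 2)), ids), contigs, "CTRL",
                      eps=0.0)


class TestFlagging:
    def test_small_bin_with_control_content_flagged(self):
        b = ContigBin("b0", ["x"], total_length=2_000_000, control_length=2_000)
        # control fraction 0.0002 of a 10 Mbp control > 0.01% and < 10 Mbp
        assert flag_artefact_bins([b], control_total_length=10_000_000) == {"b0"}

    def test_large_bin_never_flagged(self):
        b = ContigBin("b0", ["x"], total_length=12_000_000, control_length=6_000_000)
        assert flag_artefact_bins([b], control_total_length=12_000_000) == set()

    def test_zero_control_content_not_flagged(self):
        b = ContigBin("b0", ["x"], total_length=1_000_000, control_length=0)
        assert flag_artefact_bins([b], control_total_length=1_000_000) == set()

    def test_boundaries_are_strict(self):
        # exactly 10 Mbp and exactly 0.01% both fail the strict inequalities
        at_length = ContigBin("b1", ["x"], 10_000_000, 10_000_000)
        at_fraction = ContigBin("b2", ["x"], 1_000_000, 100)
        flagged = flag_artefact_bins([at_length, at_fraction],
                                     control_total_length=1_000_000)
        assert flagged == set()
        just_over = ContigBin("b3", ["x"], 9_999_999, 101)
        assert flag_artefact_bins([just_over], 1_000_000) == {"b3"}


class TestApply:
    def test_no_flags_identity(self):
        contigs = [Contig("a", "S", "ACGT"), Contig("b", "S", "ACGT")]
        curated, report = apply_decontamination(contigs, [], set(), set())
        assert curated == contigs and report.empty

    def test_screen_takes_precedence_over_bin(self):
        contigs = [Contig("a", "S", "ACGT")]
        bins = [ContigBin("b0", ["a"], 4, 0)]
        curated, report = apply_decontamination(contigs, bins, {"b0"}, {"a"})
        assert curated == []
        assert report.iloc[0]["reason"] == "screen"

    def test_curated_and_removed_partition_the_input(self):
        contigs = [Contig(f"c{i}", "S", "ACGTACGT") for i in range(6)]
        bins = [ContigBin("b0", ["c1", "c2"], 16, 8)]
        curated, report = apply_decontamination(contigs, bins, {"b0"}, {"c0"})
        curated_ids = {c.contig_id for c in curated}
        removed_ids = set(report["contig_id"])
        assert curated_ids | removed_ids == {f"c{i}" for i in range(6)}
        assert curated_ids & removed_ids == set()


class TestEndToEnd:
    def test_contaminant_genome_removed_from_low_biomass_sample(self):
        # a sample whose contigs mix a bona fide genome with the control's
        # contaminant genome loses exactly the contaminant-derived contigs
        rng = np.random.default_rng(21)
        bona = random_genome(80_000, 0.40, rng)
        contam = random_genome(80_000, 0.65, rng)
        control = [Contig(f"ctl{i}", "CTRL",
                          decode_sequence(contam[i * 4000:(i + 1) * 4000]))
                   for i in range(20)]
        sample = []
        for i in range(16):
            sample.append(Contig(f"bf{i}", "S",
                                 decode_sequence(bona[i * 5000:(i + 1) * 5000])))
        for i in range(10):
            sample.append(Contig(f"ct{i}", "S",
                                 decode_sequence(contam[i * 4000 + 2000:
                                                        i * 4000 + 6000])))
        curated, report = decontaminate_sample(sample, control)
        removed = set(report["contig_id"])
        assert {f"ct{i}" for i in range(10)} <= removed
        assert not any(cid.startswith("bf") for cid in removed)
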