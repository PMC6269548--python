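"""Parameter-recovery benchmarks on synthetic cohorts.

These routines generate a cohort, run the relevant pipeline stages, and
score the calls against the generator's ground truth: contaminant-removal
recall and bona fide contig loss, strain-sharing precision/recall, the
fixation-index ordering between transmission and within-host drift, and
the planted functional contrast (LPS-like pathway enrichment and the
Gram-negative abundance difference between delivery groups).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import functional as fn
from . import linking as lk
from . import popgen as pg
from .pipeline import decontaminate_cohort, evaluate_calls, sharing_calls_read_based
from .simulate import CohortConfig, SyntheticCohort, generate_cohort


@dataclass
class CohortBenchmark:
    """Recovery scores for one synthetic cohort."""

    seed: int
    decontam_tp: int = 0
    decontam_fp: int = 0
    decontam_fn: int = 0
    bona_fide_total: int = 0
    sharing_tp: int = 0
    sharing_fp: int = 0
    sharing_fn: int = 0
    fst_ordering_wins: int = 0
    fst_ordering_total: int = 0
    fst_values: list[tuple[float, float]] = field(default_factory=list)
    lps_q: float = float("nan")
    gramneg_vd_day3: float = float("nan")
    gramneg_csd_day3: float = float("nan")

    @property
    def decontam_recall(self) -> float:
        denom = self.decontam_tp + self.decontam_fn
        return self.decontam_tp / denom if denom else float("nan")

    @property
    def bona_fide_loss(self) -> float:
        return (self.decontam_fp / self.bona_fide_total
                if self.bona_fide_total else float("nan"))

    @property
    def sharing_precision(self) -> float:
        denom = self.sharing_tp + self.sharing_fp
        return self.sharing_tp / denom if denom else float("nan")

    @property
    def sharing_recall(self) -> float:
        denom = self.sharing_tp + self.sharing_fn
        return self.sharing_tp / denom if denom else float("nan")


def curated_markers(cohort: SyntheticCohort, curated: dict) -> dict[str, list]:
    markers = {}
    for sid, contigs in curated.items():
        surviving = {c.contig_id for c in contigs}
        markers[sid] = [m for m in cohort.markers[sid] if m.contig_id in surviving]
    return markers


def fst_ordering(cohort: SyntheticCohort, curated_markers: dict[str, list],
                 rng: np.random.Generator
                 ) -> tuple[int, int, list[tuple[float, float]]]:
    """Count transmitted strains with F_ST(mother, day3) > F_ST(day3, day5).

    Only strains whose mother, day-3 and day-5 pileups pass the coverage,
    breadth and completeness gates enter the comparison.  Returns
    (wins, total comparable strains, list of (F_ST(mother,day3),
    F_ST(day3,day5)) pairs).
    """
    genome_families: dict[tuple[str, str], set[int]] = {}
    for sid, markers in curated_markers.items():
        for m in markers:
            gid = cohort.truth.contig_sources.get(m.contig_id)
            if gid:
                genome_families.setdefault((gid, sid), set()).add(m.family_id)
    wins = total = 0
    values: list[tuple[float, float]] = []
    for pair_id, gid in sorted(cohort.truth.transmitted):
        samples = [f"{pair_id}M-F", f"{pair_id}N-D3", f"{pair_id}N-D5"]
        qualified = {}
        for sid in samples:
            pile = cohort.pileups.get((gid, sid))
            if pile is None:
                break
            completeness = len(genome_families.get((gid, sid), set())) / lk.N_MARKER_FAMILIES
            ok, _ = pg.qualify_genome_sample(
                pg.CoverageSummary.from_pileup(pile, completeness))
            if not ok:
                break
            qualified[sid] = pg.filter_pileup(pg.downsample_to_median(pile, 20.0, rng))
        if len(qualified) < 3:
            continue
        try:
            loci = pg.intersect_loci(qualified.values())
        except pg.EmptyIntersectionError:
            continue
        mom, d3, d5 = samples
        f_m3 = pg.compute_fst(qualified[mom], qualified[d3], loci)
        f_35 = pg.compute_fst(qualified[d3], qualified[d5], loci)
        if np.isnan(f_m3) or np.isnan(f_35):
            continue
        total += 1
        wins += f_m3 > f_35
        values.append((f_m3, f_35))
    return wins, total, values


def functional_contrast(cohort: SyntheticCohort, curated: dict
                        ) -> tuple[float, dict[str, float]]:
    """LPS-like pathway enrichment q-value and Gram-negative day-3 means.

    The KO table is built from genes on curated contigs; Gram-negative
    fractions are coverage-weighted genus abundances of curated contigs.
    """
    surviving = {sid: {c.contig_id for c in contigs} for sid, contigs in curated.items()}
    assignments: dict[str, str | None] = {}
    hits_all = []
    for sample in cohort.samples:
        sid = sample.sample_id
        hits = [h for h in cohort.gene_hits[sid]
                if sid not in surviving or cohort.gene_contig[h.gene_id] in surviving[sid]]
        n_targets = max(len(hits), 1)
        for h in hits:
            assignments[h.gene_id] = fn.assign_best_ko(h, n_targets)
        hits_all.extend(hits)
    table = fn.aggregate_ko_counts(assignments, hits_all)
    groups = {s.sample_id: (s.group or "") for s in cohort.samples}
    days = {s.sample_id: s.day for s in cohort.samples}
    individuals = {s.sample_id: s.individual_id for s in cohort.samples}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        diff = fn.differential_kos(table, groups, days, individuals=individuals)
    da = {r.ko for r in diff if r.da}
    universe = set(table.counts.columns)
    enrichment = fn.pathway_enrichment(
        da, universe, {pw: kos & universe for pw, kos in cohort.pathway_map.items()})
    lps_q = float(enrichment.loc[enrichment.pathway == "lps_biosynthesis", "q"].iloc[0])

    gram_means = {}
    meta = {s.sample_id: s for s in cohort.samples}
    for group in ("VD", "CSD"):
        fractions = []
        for sid, contigs in curated.items():
            s = meta[sid]
            if s.group != group or s.day != 3:
                continue
            genus_ab: dict[str, float] = {}
            for c in contigs:
                gid = cohort.truth.contig_sources[c.contig_id]
                genus = cohort.genomes[gid].genus
                genus_ab[genus] = genus_ab.get(genus, 0.0) + \
                    c.length * cohort.contig_coverage.get(c.contig_id, 0.0)
            total = sum(genus_ab.values())
            if total == 0:
                continue
            genus_ab = {g: v / total for g, v in genus_ab.items()}
            fractions.append(fn.gram_fraction(genus_ab, cohort.gram_table)["negative"])
        gram_means[group] = float(np.mean(fractions)) if fractions else float("nan")
    return lps_q, gram_means


def benchmark_cohort(config: CohortConfig) -> CohortBenchmark:
    """Generate one cohort, run decontamination, strain tracking, population
    genomics and functional analysis, and score everything against truth."""
    cohort = generate_cohort(config)
    bench = CohortBenchmark(seed=config.seed)

    curated, report = decontaminate_cohort(cohort)
    removed = set(report["contig_id"])
    truth_contaminants = cohort.truth.contaminant_contigs
    m = evaluate_calls(removed, truth_contaminants, "decontamination")
    bench.decontam_tp, bench.decontam_fp, bench.decontam_fn = m.tp, m.fp, m.fn
    bench.bona_fide_total = sum(len(cohort.contigs[s.sample_id])
                                for s in cohort.samples if s.role != "control") \
        - len(truth_contaminants)

    markers = curated_markers(cohort, curated)
    calls, clade_genome, _ = sharing_calls_read_based(cohort, markers)
    shared = {(c.pair_id, clade_genome.get(c.clade_id)) for c in calls if c.shared}
    shared = {t for t in shared if t[1] is not None}
    m = evaluate_calls(shared, cohort.truth.transmitted, "sharing")
    bench.sharing_tp, bench.sharing_fp, bench.sharing_fn = m.tp, m.fp, m.fn

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 271]))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        (bench.fst_ordering_wins, bench.fst_ordering_total,
         bench.fst_values) = fst_ordering(cohort, markers, rng)

    bench.lps_q, gram_means = functional_contrast(cohort, curated)
    bench.gramneg_vd_day3 = gram_means.get("VD", float("nan"))
    bench.gramneg_csd_day3 = gram_means.get("CSD", float("nan"))
    return bench


def null_differential_pvalues(config: CohortConfig) -> np.ndarray:
    """Raw per-comparison rank-sum p-values of every KO under a null cohort
    (exchangeable delivery groups), for type-I-error estimation."""
    cohort = generate_cohort(config)
    assignments: dict[str, str | None] = {}
    hits_all = []
    for sample in cohort.samples:
        hits = cohort.gene_hits[sample.sample_id]
        n_targets = max(len(hits), 1)
        for h in hits:
            assignments[h.gene_id] = fn.assign_best_ko(h, n_targets)
        hits_all.extend(hits)
    table = fn.aggregate_ko_counts(assignments, hits_all)
    groups = {s.sample_id: (s.group or "") for s in cohort.samples}
    days = {s.sample_id: s.day for s in cohort.samples}
    individuals = {s.sample_id: s.individual_id for s in cohort.samples}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        diff = fn.differential_kos(table, groups, days, individuals=individuals)
    return np.array([p for r in diff for p in r.p_values.values()])
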