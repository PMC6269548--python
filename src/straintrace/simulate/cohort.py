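"""Synthetic paired mother-neonate cohorts with machine-readable ground truth.

The generator emulates the statistical structure the downstream analysis
assumes: mothers sampled before delivery carry strain populations with
within-host allele-frequency spectra; neonates sampled on days 1/3/5
receive maternal strains through a transmission bottleneck with group- and
class-dependent probabilities (vaginally delivered neonates preferentially
receive enteric Gram-negative strains, caesarean-born neonates
skin-associated ones); low-biomass samples and a cell-culture control
carry contaminant genomes; and each genome has a KO repertoire, with an
LPS-biosynthesis-like pathway restricted to Gram-negative genomes.

Reads are never simulated: allele-count pileup columns are the atomic unit
of sequence evidence, which is exactly what the population-genomic
formulas consume.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..decontam import Contig
from ..functional import GeneHit
from ..linking import MarkerGene
from ..popgen import Pileup
from .config import (CohortConfig, GENOME_CLASSES, GENUS_GRAM, GENUS_POOL,
                     N_MARKER_FAMILIES)
from . import sequences as seqlib

REFERENCE_HOST = "__reference__"  # pseudo-individual for invariant contaminant strains


@dataclass(frozen=True)
class SampleMeta:
    sample_id: str
    individual_id: str
    pair_id: str | None
    role: str          # mother | neonate | control
    body_site: str     # faecal | vaginal | cell_culture
    day: int | None
    group: str | None  # VD | CSD | CSD_SGA | None for control


@dataclass
class GenomeRecord:
    genome_id: str
    genome_class: str
    genus: str
    gram: str
    sequence: np.ndarray                 # uint8 base codes
    kos: frozenset[str]
    markers: dict[int, str]              # family -> reference amino-acid sequence
    marker_positions: dict[int, int]     # family -> genome position

    @property
    def length(self) -> int:
        return self.sequence.size


@dataclass
class Strain:
    """One individual's population of one genome."""

    individual_id: str
    genome_id: str
    consensus: np.ndarray                # uint8 codes
    markers: dict[int, str]
    poly_positions: np.ndarray           # sorted genome positions
    minor_alleles: np.ndarray            # uint8 codes, parallel to poly_positions


@dataclass
class GroundTruth:
    """Everything needed to score the pipeline's calls against the simulation."""

    transmitted: set[tuple[str, str]]                      # (pair_id, genome_id)
    contaminant_contigs: set[str]
    true_allele_freqs: dict[tuple[str, str], tuple[np.ndarray, np.ndarray]]
    true_pi: dict[tuple[str, str], float]
    planted_da_kos: set[str]
    gram_labels: dict[str, str]
    contig_sources: dict[str, str]                         # contig_id -> genome_id

    def allele_freq(self, genome_id: str, sample_id: str, position: int) -> np.ndarray:
        """True allele-frequency vector (A,C,G,T) at one position; consensus
        positions have frequency 1 on the consensus base."""
        positions, freqs = self.true_allele_freqs[(genome_id, sample_id)]
        idx = np.searchsorted(positions, position)
        if idx < positions.size and positions[idx] == position:
            return freqs[idx]
        raise KeyError(f"position {position} is not polymorphic; "
                       "consensus frequency is 1")


@dataclass
class SyntheticCohort:
    config: CohortConfig
    genomes: dict[str, GenomeRecord]
    samples: list[SampleMeta]
    strains: dict[tuple[str, str], Strain]                 # (individual, genome)
    abundances: dict[str, dict[str, float]]                # sample -> genome -> rel ab
    contigs: dict[str, list[Contig]]                       # sample -> contigs
    contig_coverage: dict[str, float]                      # contig -> mean depth
    markers: dict[str, list[MarkerGene]]                   # sample -> markers
    pileups: dict[tuple[str, str], Pileup]                 # (genome, sample)
    gene_hits: dict[str, list[GeneHit]]                    # sample -> gene hits
    gene_contig: dict[str, str]                            # gene -> contig
    pathway_map: dict[str, set[str]]
    gram_table: dict[str, str]
    truth: GroundTruth

    @property
    def control_sample(self) -> SampleMeta:
        return next(s for s in self.samples if s.role == "control")

    def sample_meta(self, sample_id: str) -> SampleMeta:
        return next(s for s in self.samples if s.sample_id == sample_id)

    def pairs(self) -> list[str]:
        return sorted({s.pair_id for s in self.samples if s.pair_id is not None})


# ------------------------------------------------------------------ internals

def _build_genomes(config: CohortConfig, rng: np.random.Generator
                   ) -> dict[str, GenomeRecord]:
    genomes: dict[str, GenomeRecord] = {}
    idx = 0
    genus_counter: dict[str, int] = {}
    for cls in GENOME_CLASSES:
        for _ in range(config.class_counts.get(cls, 0)):
            idx += 1
            gid = f"G{idx:02d}"
            pool = GENUS_POOL[cls]
            genus = pool[genus_counter.get(cls, 0) % len(pool)]
            genus_counter[cls] = genus_counter.get(cls, 0) + 1
            seq = seqlib.random_genome(config.genome_length, config.gc_by_class[cls], rng)
            lo, hi = config.marker_length_range
            markers = {fam: seqlib.random_protein(int(rng.integers(lo, hi + 1)), rng)
                       for fam in range(1, N_MARKER_FAMILIES + 1)}
            positions = {fam: int((fam - 0.5) * config.genome_length / N_MARKER_FAMILIES)
                         for fam in range(1, N_MARKER_FAMILIES + 1)}
            genomes[gid] = GenomeRecord(gid, cls, genus, GENUS_GRAM.get(genus, "unknown"),
                                        seq, frozenset(), markers, positions)
    return genomes


def _assign_kos(config: CohortConfig, genomes: dict[str, GenomeRecord],
                rng: np.random.Generator) -> tuple[dict[str, set[str]], set[str]]:
    """KO repertoires per genome and the pathway map.

    The universe is partitioned into a core shared by every genome,
    class-specific pools, and an accessory pool; every Gram-negative enteric
    genome carries the full LPS-like pathway, which is drawn from the
    Gram-negative pool only.
    """
    universe = [f"K{i + 1:05d}" for i in range(config.n_kos)]
    fracs = {"core": 0.45, "enteric_gramneg": 0.10, "enteric_grampos": 0.075,
             "skin_firmicute": 0.05, "contaminant": 0.05}
    pools: dict[str, list[str]] = {}
    start = 0
    for name, frac in fracs.items():
        n = int(round(frac * config.n_kos))
        pools[name] = universe[start:start + n]
        start += n
    pools["accessory"] = universe[start:]
    lps_size = config.pathway_map_spec["lps_biosynthesis"]
    if lps_size > len(pools["enteric_gramneg"]):
        raise ValueError("pathway_map_spec: lps_biosynthesis larger than the "
                         "Gram-negative KO pool")
    lps_kos = pools["enteric_gramneg"][:lps_size]
    ko_sets: dict[str, set[str]] = {}
    for gid, g in sorted(genomes.items()):
        kos = set(pools["core"])
        class_pool = pools[g.genome_class]
        take = rng.random(len(class_pool)) < 0.85
        kos |= {k for k, t in zip(class_pool, take) if t}
        if g.genome_class == "enteric_gramneg":
            kos |= set(lps_kos)
        acc = pools["accessory"]
        take = rng.random(len(acc)) < 0.6
        kos |= {k for k, t in zip(acc, take) if t}
        ko_sets[gid] = kos
    pathway_map: dict[str, set[str]] = {}
    for pw, size in sorted(config.pathway_map_spec.items()):
        if pw == "lps_biosynthesis":
            pathway_map[pw] = set(lps_kos)
        else:
            pathway_map[pw] = set(rng.choice(universe, size=min(size, len(universe)),
                                             replace=False).tolist())
    return ko_sets, pathway_map, set(lps_kos)


def _make_samples(config: CohortConfig) -> list[SampleMeta]:
    samples: list[SampleMeta] = []
    pair_no = 0
    for group in ("VD", "CSD", "CSD_SGA"):
        for _ in range(config.n_pairs_per_group.get(group, 0)):
            pair_no += 1
            pid = f"P{pair_no:02d}"
            mother, neonate = f"{pid}M", f"{pid}N"
            samples.append(SampleMeta(f"{mother}-F", mother, pid, "mother",
                                      "faecal", None, group))
            for day in config.days:
                samples.append(SampleMeta(f"{neonate}-D{day}", neonate, pid,
                                          "neonate", "faecal", day, group))
    samples.append(SampleMeta("CTRL", "CTRL", None, "control", "cell_culture",
                              None, None))
    return samples


def _strain_from_reference(genome: GenomeRecord, individual: str,
                           config: CohortConfig, rng: np.random.Generator
                           ) -> tuple[Strain, np.ndarray]:
    consensus, _ = seqlib.mutate_strain(genome.sequence, config.strain_divergence, rng)
    markers = {fam: seqlib.mutate_protein(seq, config.strain_divergence, rng)
               for fam, seq in sorted(genome.markers.items())}
    n_poly = int(round(config.poly_site_fraction * genome.length))
    pos = np.sort(rng.choice(genome.length, size=n_poly, replace=False))
    minor = ((consensus[pos].astype(np.int64) + rng.integers(1, 4, size=n_poly)) % 4
             ).astype(np.uint8)
    a, b = config.within_host_maf
    maf = rng.beta(a, b, size=n_poly)
    return Strain(individual, genome.genome_id, consensus, markers, pos, minor), maf


def _strain_from_mother(mother: Strain, genome: GenomeRecord, individual: str,
                        config: CohortConfig, rng: np.random.Generator) -> Strain:
    consensus, _ = seqlib.mutate_strain(mother.consensus, config.transmission_snv_rate, rng)
    markers = {fam: seqlib.mutate_protein(seq, config.transmission_marker_drift, rng)
               for fam, seq in sorted(mother.markers.items())}
    return Strain(individual, genome.genome_id, consensus, markers,
                  mother.poly_positions.copy(), mother.minor_alleles.copy())


def _perturb_freqs(freqs: np.ndarray, scale: float, rng: np.random.Generator
                   ) -> np.ndarray:
    """Drift allele frequencies: Beta(f/s, (1-f)/s) around each frequency f."""
    out = freqs.copy()
    interior = (freqs > 0) & (freqs < 1)
    if interior.any():
        f = freqs[interior]
        out[interior] = rng.beta(f / scale, (1 - f) / scale)
    return out


def _true_pi(maf: np.ndarray, genome_length: int) -> float:
    return float((2 * maf * (1 - maf)).sum() / genome_length)


def _freq_matrix(strain: Strain, maf: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    n = strain.poly_positions.size
    freqs = np.zeros((n, 4))
    cons = strain.consensus[strain.poly_positions]
    freqs[np.arange(n), cons] = 1.0 - maf
    freqs[np.arange(n), strain.minor_alleles] = maf
    return strain.poly_positions.copy(), freqs


def _simulate_pileup(genome: GenomeRecord, strain: Strain, maf: np.ndarray,
                     mean_depth: float, sample_id: str,
                     rng: np.random.Generator) -> Pileup:
    L = genome.length
    depth = rng.poisson(mean_depth, L).astype(np.int64)
    counts = np.zeros((L, 4), dtype=np.uint16)
    counts[np.arange(L), strain.consensus] = depth
    pos = strain.poly_positions
    if pos.size:
        k = rng.binomial(depth[pos], maf)
        counts[pos, strain.consensus[pos]] -= k.astype(np.uint16)
        counts[pos, strain.minor_alleles] += k.astype(np.uint16)
    return Pileup(genome.genome_id, sample_id, counts)


def _emit_sample_contigs(sample: SampleMeta, present: list[str],
                         genomes: dict[str, GenomeRecord],
                         strains: dict[tuple[str, str], Strain],
                         config: CohortConfig, rng: np.random.Generator):
    """Tile each present genome's consensus into contigs with anonymous ids."""
    pieces: list[tuple[str, str, dict[int, int]]] = []  # (seq, genome, fam->piece idx)
    for gid in present:
        genome = genomes[gid]
        strain = strains[(_strain_host(sample, gid, genomes), gid)]
        lengths = seqlib.contig_lengths(genome.length, rng,
                                        median=config.contig_length_median,
                                        sigma=config.contig_length_sigma,
                                        min_length=config.contig_min_length)
        offset = 0
        bounds = []
        for ln in lengths:
            seq = seqlib.decode_sequence(strain.consensus[offset:offset + ln])
            bounds.append((offset, offset + ln))
            pieces.append((seq, gid, {}))
            offset += ln
        base_idx = len(pieces) - len(lengths)
        for fam, mpos in genome.marker_positions.items():
            for j, (lo, hi) in enumerate(bounds):
                if lo <= mpos < hi:
                    pieces[base_idx + j][2][fam] = mpos
                    break
    order = rng.permutation(len(pieces))
    contigs, sources, marker_contig = [], {}, {}
    for new_idx, old_idx in enumerate(order):
        seq, gid, fams = pieces[old_idx]
        cid = f"{sample.sample_id}_c{new_idx:04d}"
        contigs.append(Contig(cid, sample.sample_id, seq))
        sources[cid] = gid
        for fam in fams:
            marker_contig[(gid, fam)] = cid
    return contigs, sources, marker_contig


def _strain_host(sample: SampleMeta, genome_id: str,
                 genomes: dict[str, GenomeRecord]) -> str:
    if genomes[genome_id].genome_class == "contaminant":
        return REFERENCE_HOST
    return sample.individual_id


# ------------------------------------------------------------------ generator

def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Generate one seeded cohort; deterministic for a fixed config."""
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    rng_genomes, rng_design, rng_strains, rng_pileups, rng_contigs, rng_genes = (
        np.random.default_rng(child) for child in ss.spawn(6))

    genomes = _build_genomes(config, rng_genomes)
    ko_sets, pathway_map, lps_kos = _assign_kos(config, genomes, rng_genomes)
    for gid, kos in ko_sets.items():
        genomes[gid].kos = frozenset(kos)
    gramneg_union = set().union(*(ko_sets[g] for g, rec in genomes.items()
                                  if rec.genome_class == "enteric_gramneg"))
    other_union = set().union(*(ko_sets[g] for g, rec in genomes.items()
                                if rec.genome_class != "enteric_gramneg"))
    planted_da = gramneg_union - other_union

    samples = _make_samples(config)
    contaminants = sorted(g for g, rec in genomes.items()
                          if rec.genome_class == "contaminant")
    bona_fide = sorted(g for g in genomes if g not in contaminants)

    # ------------------------------------------------ carriage & transmission
    mothers = sorted({s.individual_id for s in samples if s.role == "mother"})
    pair_of = {s.individual_id: s.pair_id for s in samples}
    group_of = {s.pair_id: s.group for s in samples if s.pair_id}
    mother_carries: dict[str, list[str]] = {}
    for mom in mothers:
        carried = [g for g in bona_fide
                   if rng_design.random() < config.mother_carriage.get(
                       genomes[g].genome_class, 0.0)]
        if not carried:
            carried = [bona_fide[0]]
        mother_carries[mom] = carried
    transmitted: set[tuple[str, str]] = set()
    neonate_presence: dict[str, list[tuple[str, bool]]] = {}  # neonate -> (genome, from_mother)
    neonates = sorted({s.individual_id for s in samples if s.role == "neonate"})
    for neo in neonates:
        pid = pair_of[neo]
        mom = f"{pid}M"
        group = group_of[pid]
        present: list[tuple[str, bool]] = []
        for g in bona_fide:
            cls = genomes[g].genome_class
            p_trans = config.transmission_prob.get(group, {}).get(cls, 0.0)
            if g in mother_carries[mom] and rng_design.random() < p_trans:
                transmitted.add((pid, g))
                present.append((g, True))
            elif rng_design.random() < config.env_acquisition.get(cls, 0.0):
                present.append((g, False))
        # the neonatal gut is never sterile: facultative skin-associated
        # colonisers establish in every neonate
        skin = [g for g in bona_fide
                if genomes[g].genome_class == "skin_firmicute"]
        if skin and not any(genomes[g].genome_class == "skin_firmicute"
                            for g, _ in present):
            present.append((skin[int(rng_design.integers(len(skin)))], False))
        if not present:
            present = [(bona_fide[int(rng_design.integers(len(bona_fide)))], False)]
        present.sort()
        neonate_presence[neo] = present

    # ------------------------------------------------------------- abundances
    abundances: dict[str, dict[str, float]] = {}
    for s in samples:
        if s.role == "mother":
            carried = mother_carries[s.individual_id]
            alpha = np.array([config.mother_alpha.get(genomes[g].genome_class, 1.0)
                              for g in carried])
            ab = rng_design.dirichlet(alpha)
            abundances[s.sample_id] = dict(zip(carried, ab.tolist()))
        elif s.role == "neonate":
            present = [g for g, _ in neonate_presence[s.individual_id]]
            alpha = np.array([config.neonate_alpha.get(genomes[g].genome_class, 1.0)
                              for g in present])
            if s.group == "VD":
                # vaginally delivered neonates: maternal Gram-negative enteric
                # strains establish at lps_effect_size-fold concentration
                boost = np.array([config.lps_effect_size
                                  if genomes[g].genome_class == "enteric_gramneg" else 1.0
                                  for g in present])
                alpha = alpha * boost
            ab = rng_design.dirichlet(alpha)
            ab = ab * (1.0 - config.contaminant_load)
            entry = dict(zip(present, ab.tolist()))
            for g in contaminants:
                entry[g] = config.contaminant_load / len(contaminants) if contaminants else 0.0
            abundances[s.sample_id] = {g: v for g, v in entry.items() if v > 0}
        else:  # control
            abundances[s.sample_id] = {g: 1.0 / len(contaminants) for g in contaminants} \
                if contaminants else {}
    # day-to-day compositional drift within each neonate: every day's bona
    # fide shares are drawn around the base composition of the first day
    for neo in neonates:
        base = abundances[f"{neo}-D{config.days[0]}"]
        bona = sorted(g for g in base if g not in contaminants)
        cont = {g: v for g, v in base.items() if g in contaminants}
        shares = np.array([base[g] for g in bona])
        shares = shares / shares.sum()
        for day in config.days:
            drifted = rng_design.dirichlet(shares * config.day_abundance_concentration)
            entry = dict(zip(bona, (drifted * (1.0 - config.contaminant_load)).tolist()))
            entry.update(cont)
            abundances[f"{neo}-D{day}"] = {g: v for g, v in entry.items() if v > 0}

    # ----------------------------------------------------------------- strains
    strains: dict[tuple[str, str], Strain] = {}
    maternal_maf: dict[tuple[str, str], np.ndarray] = {}
    for g in contaminants:
        genome = genomes[g]
        strains[(REFERENCE_HOST, g)] = Strain(
            REFERENCE_HOST, g, genome.sequence.copy(), dict(genome.markers),
            np.empty(0, dtype=np.int64), np.empty(0, dtype=np.uint8))
    for mom in mothers:
        for g in mother_carries[mom]:
            strain, maf = _strain_from_reference(genomes[g], mom, config, rng_strains)
            strains[(mom, g)] = strain
            maternal_maf[(mom, g)] = maf
    sample_maf: dict[tuple[str, str], np.ndarray] = {}  # (genome, sample) -> minor freqs
    for mom in mothers:
        sid = f"{mom}-F"
        for g in mother_carries[mom]:
            sample_maf[(g, sid)] = maternal_maf[(mom, g)]
    for neo in neonates:
        pid = pair_of[neo]
        mom = f"{pid}M"
        for g, from_mother in neonate_presence[neo]:
            if from_mother:
                strain = _strain_from_mother(strains[(mom, g)], genomes[g], neo,
                                             config, rng_strains)
                base = maternal_maf[(mom, g)]
            else:
                strain, base = _strain_from_reference(genomes[g], neo, config, rng_strains)
            strains[(neo, g)] = strain
            freqs = _perturb_freqs(base, config.bottleneck_shift, rng_strains)
            sample_maf[(g, f"{neo}-D{config.days[0]}")] = freqs
            for day in config.days[1:]:
                freqs = _perturb_freqs(freqs, config.day_drift, rng_strains)
                sample_maf[(g, f"{neo}-D{day}")] = freqs

    # ---------------------------------------------------------------- pileups
    pileups: dict[tuple[str, str], Pileup] = {}
    true_allele_freqs: dict[tuple[str, str], tuple[np.ndarray, np.ndarray]] = {}
    true_pi: dict[tuple[str, str], float] = {}
    for s in samples:
        site_depth = config.depth_mean.get(s.body_site, 0.0)
        for g, ab in sorted(abundances[s.sample_id].items()):
            host = _strain_host(s, g, genomes)
            strain = strains[(host, g)]
            maf = sample_maf.get((g, s.sample_id),
                                 np.zeros(strain.poly_positions.size))
            pileups[(g, s.sample_id)] = _simulate_pileup(
                genomes[g], strain, maf, site_depth * ab, s.sample_id, rng_pileups)
            true_allele_freqs[(g, s.sample_id)] = _freq_matrix(strain, maf)
            true_pi[(g, s.sample_id)] = _true_pi(maf, genomes[g].length)

    # ---------------------------------------------------------------- contigs
    contigs: dict[str, list[Contig]] = {}
    contig_coverage: dict[str, float] = {}
    markers: dict[str, list[MarkerGene]] = {}
    contig_sources: dict[str, str] = {}
    contaminant_contigs: set[str] = set()
    for s in samples:
        present = sorted(abundances[s.sample_id])
        sample_contigs, sources, marker_contig = _emit_sample_contigs(
            s, present, genomes, strains, config, rng_contigs)
        contigs[s.sample_id] = sample_contigs
        contig_sources.update(sources)
        site_depth = config.depth_mean.get(s.body_site, 0.0)
        for c in sample_contigs:
            contig_coverage[c.contig_id] = site_depth * abundances[s.sample_id][sources[c.contig_id]]
        if s.role != "control":
            contaminant_contigs |= {cid for cid, gid in sources.items()
                                    if genomes[gid].genome_class == "contaminant"}
        sample_markers = []
        for g in present:
            host = _strain_host(s, g, genomes)
            strain = strains[(host, g)]
            for fam in sorted(strain.markers):
                cid = marker_contig[(g, fam)]
                sample_markers.append(MarkerGene(
                    marker_id=f"{cid}.m{fam:02d}", family_id=fam,
                    sequence=strain.markers[fam], sample_id=s.sample_id,
                    individual_id=s.individual_id, contig_id=cid))
        markers[s.sample_id] = sample_markers

    # -------------------------------------------------------------- gene hits
    universe = [f"K{i + 1:05d}" for i in range(config.n_kos)]
    gene_hits: dict[str, list[GeneHit]] = {}
    gene_contig: dict[str, str] = {}
    for s in samples:
        hits: list[GeneHit] = []
        gene_no = 0
        for g in sorted(abundances[s.sample_id]):
            ab = abundances[s.sample_id][g]
            kos = sorted(genomes[g].kos)
            reads = rng_genes.poisson(config.gene_read_depth * ab, len(kos))
            scores = np.clip(rng_genes.normal(150.0, 30.0, len(kos)), 25.0, None)
            weak = rng_genes.random(len(kos)) < 0.05
            scores[weak] = rng_genes.uniform(1.0, 8.0, int(weak.sum()))
            decoy_idx = rng_genes.integers(0, len(universe), size=(len(kos), 2))
            decoy_frac = rng_genes.uniform(0.3, 0.8, size=(len(kos), 2))
            genome_cids = [c.contig_id for c in contigs[s.sample_id]
                           if contig_sources[c.contig_id] == g]
            cid_pick = rng_genes.integers(0, len(genome_cids), len(kos))
            for i, ko in enumerate(kos):
                if reads[i] == 0:
                    continue
                gene_no += 1
                gene_id = f"{s.sample_id}_g{gene_no:05d}"
                cand = {ko: float(scores[i])}
                for j in range(2):
                    decoy = universe[decoy_idx[i, j]]
                    if decoy not in cand:
                        cand[decoy] = float(scores[i] * decoy_frac[i, j])
                hits.append(GeneHit(gene_id, s.sample_id, cand, int(reads[i])))
                gene_contig[gene_id] = genome_cids[cid_pick[i]]
        gene_hits[s.sample_id] = hits

    gram_table = {genomes[g].genus: genomes[g].gram for g in sorted(genomes)}
    truth = GroundTruth(
        transmitted=transmitted,
        contaminant_contigs=contaminant_contigs,
        true_allele_freqs=true_allele_freqs,
        true_pi=true_pi,
        planted_da_kos=planted_da,
        gram_labels=gram_table,
        contig_sources=contig_sources,
    )
    return SyntheticCohort(
        config=config, genomes=genomes, samples=samples, strains=strains,
        abundances=abundances, contigs=contigs, contig_coverage=contig_coverage,
        markers=markers, pileups=pileups, gene_hits=gene_hits,
        gene_contig=gene_contig, pathway_map=pathway_map, gram_table=gram_table,
        truth=truth)
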