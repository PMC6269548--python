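"""Cohort configuration: the study design knobs of the synthetic generator.

The defaults encode a scaled-down paired mother-neonate cohort sampled on
days 1/3/5 after delivery, with three delivery groups (vaginal delivery,
caesarean section, caesarean section + small-for-gestational-age), a
cell-culture negative-control sample, class-dependent transmission
probabilities, and a Gram-negative-linked LPS-biosynthesis-like pathway
whose carriers are enriched in vaginally delivered neonates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping

import yaml

GROUPS = ("VD", "CSD", "CSD_SGA")
GENOME_CLASSES = ("enteric_gramneg", "enteric_grampos", "skin_firmicute", "contaminant")
BODY_SITES = ("faecal", "vaginal", "cell_culture")
N_MARKER_FAMILIES = 35

#: genera used to label synthetic genomes, by class (cycled if more genomes
#: than names); Gram labels follow the genus.
GENUS_POOL = {
    "enteric_gramneg": ("Escherichia", "Bacteroides", "Klebsiella", "Enterobacter"),
    "enteric_grampos": ("Bifidobacterium", "Enterococcus", "Lactobacillus"),
    "skin_firmicute": ("Staphylococcus", "Cutibacterium"),
    "contaminant": ("Achromobacter", "Burkholderia", "Ralstonia"),
}
GENUS_GRAM = {
    "Escherichia": "negative", "Bacteroides": "negative", "Klebsiella": "negative",
    "Enterobacter": "negative", "Achromobacter": "negative", "Burkholderia": "negative",
    "Ralstonia": "negative",
    "Bifidobacterium": "positive", "Enterococcus": "positive", "Lactobacillus": "positive",
    "Staphylococcus": "positive", "Cutibacterium": "positive",
}


def _default_pairs() -> dict[str, int]:
    # roughly half the study's 15 VD / 12 CSD / 6 CSD+SGA neonates, keeping
    # the group imbalance direction; large enough that an exact rank-sum
    # across neonates can resolve group effects after FDR control
    return {"VD": 8, "CSD": 7, "CSD_SGA": 5}


def _default_gc() -> dict[str, float]:
    return {
        "enteric_gramneg": 0.50,
        "enteric_grampos": 0.40,
        "skin_firmicute": 0.33,
        "contaminant": 0.65,
    }


def _default_class_counts() -> dict[str, int]:
    return {
        "enteric_gramneg": 3,
        "enteric_grampos": 2,
        "skin_firmicute": 2,
        "contaminant": 2,
    }


def _default_mother_alpha() -> dict[str, float]:
    # Adult gut: enteric taxa dominate, skin taxa are minor residents.
    return {"enteric_gramneg": 4.0, "enteric_grampos": 3.0, "skin_firmicute": 1.0}


def _default_neonate_alpha() -> dict[str, float]:
    # Neonatal gut: skin-associated colonisers grab large shares unless
    # displaced; enteric strains start from smaller inocula.
    return {"enteric_gramneg": 2.0, "enteric_grampos": 2.0, "skin_firmicute": 8.0}


def _default_transmission() -> dict[str, dict[str, float]]:
    # Vaginally delivered neonates preferentially receive maternal enteric
    # (especially Gram-negative) strains; caesarean-born neonates are instead
    # seeded by skin-associated taxa.  Contaminants are never transmitted.
    return {
        "VD": {"enteric_gramneg": 0.80, "enteric_grampos": 0.60,
               "skin_firmicute": 0.20, "contaminant": 0.0},
        "CSD": {"enteric_gramneg": 0.15, "enteric_grampos": 0.30,
                "skin_firmicute": 0.70, "contaminant": 0.0},
        "CSD_SGA": {"enteric_gramneg": 0.10, "enteric_grampos": 0.25,
                    "skin_firmicute": 0.70, "contaminant": 0.0},
    }


def _default_mother_carriage() -> dict[str, float]:
    return {"enteric_gramneg": 0.95, "enteric_grampos": 0.90,
            "skin_firmicute": 0.60, "contaminant": 0.0}


def _default_env_acquisition() -> dict[str, float]:
    # Environmental/hospital seeding of the neonatal gut, independent of the
    # mother: skin-associated taxa colonise readily, enteric taxa rarely.
    return {"enteric_gramneg": 0.05, "enteric_grampos": 0.10,
            "skin_firmicute": 0.70, "contaminant": 0.0}


def _default_depth() -> dict[str, float]:
    return {"faecal": 120.0, "vaginal": 80.0, "cell_culture": 60.0}


def _default_pathways() -> dict[str, int]:
    spec = {"lps_biosynthesis": 12}
    for i in range(2, 13):
        spec[f"pathway_{i:02d}"] = 15
    return spec


@dataclass
class CohortConfig:
    """Study-design parameters of one synthetic paired cohort.

    Attributes
    ----------
    n_pairs_per_group
        Mother-neonate pairs per delivery group.
    days
        Neonatal faecal sampling days (strictly increasing); maternal samples
        are taken before delivery (day ``None``).
    n_genomes, class_counts
        Size and class composition of the genome pool; ``class_counts`` must
        sum to ``n_genomes``.
    genome_length
        Reference length in bp of every genome (scaled down from real
        genomes; >= 10 kb).
    gc_by_class
        Target GC fraction per genome class; contaminants are high-GC so the
        composition embedding can isolate them, as for the high-GC reagent
        contaminants seen in real low-biomass runs.
    transmission_prob
        (group, class) -> probability that a maternal strain seeds the
        neonate at delivery.
    mother_carriage
        class -> probability a mother carries each genome of that class.
    mother_alpha, neonate_alpha
        class -> Dirichlet concentration used when drawing relative
        abundances over the genomes present in a sample; the neonatal
        weighting favours skin-associated colonisers, the maternal one
        enteric residents.
    env_acquisition
        class -> probability a neonate acquires a genome of that class from
        the environment (an unrelated strain) when it was not transmitted;
        skin-associated taxa colonise far more readily than enteric ones.
    strain_divergence
        Expected per-site substitution rate between unrelated individuals'
        strains of the same genome.
    transmission_snv_rate, transmission_marker_drift
        Tiny consensus-level substitution rates applied to a transmitted
        strain (genome nucleotides and marker amino acids respectively).
    within_host_maf
        (alpha, beta) of the Beta distribution of within-host minor-allele
        frequencies at polymorphic sites.
    poly_site_fraction
        Fraction of genome positions that are polymorphic within a host.
    bottleneck_shift
        Allele-frequency perturbation scale at transmission: neonatal
        frequencies are drawn from Beta(f/s, (1-f)/s) around the maternal
        frequency f with s = bottleneck_shift.
    day_drift
        Same perturbation scale applied between consecutive sampling days.
    depth_mean
        body site -> mean total per-sample coverage; a genome's coverage is
        this value times its relative abundance.
    contaminant_load
        Total relative abundance of contaminant genomes in low-biomass
        samples (neonatal faecal, vaginal, cell-culture control).
    day_abundance_concentration
        Dirichlet concentration of day-to-day compositional drift within a
        neonate: each day's genome shares are drawn around the neonate's
        base composition; smaller values mean stronger day-to-day change.
    n_kos, pathway_map_spec
        KO universe size and pathway -> KO-count map; must include an
        ``lps_biosynthesis`` pathway, whose KOs are restricted to
        Gram-negative genomes.
    lps_effect_size
        Multiplicative enrichment of Gram-negative genome abundance in VD
        neonatal samples, applied to the colonisation concentration of each
        Gram-negative genome present.
    gene_read_depth
        Expected read count of a gene at relative abundance 1 (Poisson mean
        scaling for the gene -> KO hit tables).
    seed
        Base seed; all randomness derives from it.
    """

    n_pairs_per_group: dict[str, int] = field(default_factory=_default_pairs)
    days: tuple[int, ...] = (1, 3, 5)
    n_genomes: int = 9
    class_counts: dict[str, int] = field(default_factory=_default_class_counts)
    mother_alpha: dict[str, float] = field(default_factory=_default_mother_alpha)
    neonate_alpha: dict[str, float] = field(default_factory=_default_neonate_alpha)
    genome_length: int = 200_000
    gc_by_class: dict[str, float] = field(default_factory=_default_gc)
    transmission_prob: dict[str, dict[str, float]] = field(default_factory=_default_transmission)
    mother_carriage: dict[str, float] = field(default_factory=_default_mother_carriage)
    env_acquisition: dict[str, float] = field(default_factory=_default_env_acquisition)
    strain_divergence: float = 0.01
    transmission_snv_rate: float = 2e-5
    transmission_marker_drift: float = 2e-4
    within_host_maf: tuple[float, float] = (0.8, 8.0)
    poly_site_fraction: float = 0.005
    bottleneck_shift: float = 0.30
    day_drift: float = 0.02
    depth_mean: dict[str, float] = field(default_factory=_default_depth)
    contaminant_load: float = 0.18
    day_abundance_concentration: float = 12.0
    n_kos: int = 800
    pathway_map_spec: dict[str, int] = field(default_factory=_default_pathways)
    lps_effect_size: float = 4.0
    gene_read_depth: float = 600.0
    contig_length_median: int = 5000
    contig_length_sigma: float = 0.45
    contig_min_length: int = 500
    marker_length_range: tuple[int, int] = (60, 100)
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        """Raise ``ValueError`` naming the offending field on invalid input."""
        for group, n in self.n_pairs_per_group.items():
            if group not in GROUPS:
                raise ValueError(f"n_pairs_per_group: unknown group {group!r}")
            if n < 0:
                raise ValueError("n_pairs_per_group: counts must be >= 0")
        days = tuple(self.days)
        if any(b <= a for a, b in zip(days, days[1:])) or not days:
            raise ValueError("days: must be a non-empty strictly increasing sequence")
        if self.genome_length < 10_000:
            raise ValueError("genome_length: must be >= 10000 bp")
        if sum(self.class_counts.values()) != self.n_genomes:
            raise ValueError("class_counts: must sum to n_genomes")
        for cls, gc in self.gc_by_class.items():
            if cls not in GENOME_CLASSES:
                raise ValueError(f"gc_by_class: unknown class {cls!r}")
            if not 0.0 < gc < 1.0:
                raise ValueError(f"gc_by_class[{cls}]: GC fraction must be in (0,1)")
        for group, per_class in self.transmission_prob.items():
            for cls, p in per_class.items():
                if not 0.0 <= p <= 1.0:
                    raise ValueError(
                        f"transmission_prob[{group}][{cls}]: probability must be in [0,1]")
        if not 0.0 <= self.contaminant_load <= 1.0:
            raise ValueError("contaminant_load: must be in [0,1]")
        for cls, p in self.env_acquisition.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"env_acquisition[{cls}]: must be in [0,1]")
        for name, alphas in (("mother_alpha", self.mother_alpha),
                             ("neonate_alpha", self.neonate_alpha)):
            for cls, a in alphas.items():
                if a <= 0:
                    raise ValueError(f"{name}[{cls}]: concentration must be > 0")
        for cls, p in self.mother_carriage.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"mother_carriage[{cls}]: must be in [0,1]")
        if not 0.0 <= self.strain_divergence < 1.0:
            raise ValueError("strain_divergence: must be in [0,1)")
        a, b = self.within_host_maf
        if a <= 0 or b <= 0:
            raise ValueError("within_host_maf: Beta parameters must be positive")
        if not 0.0 <= self.poly_site_fraction <= 1.0:
            raise ValueError("poly_site_fraction: must be in [0,1]")
        if self.bottleneck_shift <= 0 or self.day_drift <= 0:
            raise ValueError("bottleneck_shift/day_drift: perturbation scales must be > 0")
        if self.day_abundance_concentration <= 0:
            raise ValueError("day_abundance_concentration: must be > 0")
        for site, d in self.depth_mean.items():
            if site not in BODY_SITES:
                raise ValueError(f"depth_mean: unknown body site {site!r}")
            if d < 0:
                raise ValueError(f"depth_mean[{site}]: must be >= 0")
        if self.n_kos < 1:
            raise ValueError("n_kos: must be >= 1")
        if "lps_biosynthesis" not in self.pathway_map_spec:
            raise ValueError("pathway_map_spec: must include an 'lps_biosynthesis' pathway")
        for pw, n in self.pathway_map_spec.items():
            if n < 1:
                raise ValueError(f"pathway_map_spec[{pw}]: KO count must be >= 1")
        if self.lps_effect_size <= 0:
            raise ValueError("lps_effect_size: must be > 0")

    # ------------------------------------------------------------------ io
    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_dict(cls, data: Mapping) -> "CohortConfig":
        data = dict(data)
        for key in ("days", "within_host_maf", "marker_length_range"):
            if key in data and isinstance(data[key], list):
                data[key] = tuple(data[key])
        return cls(**data)

    @classmethod
    def from_yaml(cls, path) -> "CohortConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    @classmethod
    def null(cls, seed: int = 0, **overrides) -> "CohortConfig":
        """A no-group-effect configuration for type-I-error studies.

        Transmission probabilities are equalised across delivery groups and
        the LPS effect size is set to 1, so VD/CSD/CSD_SGA KO abundances are
        exchangeable.
        """
        shared = {"enteric_gramneg": 0.4, "enteric_grampos": 0.4,
                  "skin_firmicute": 0.4, "contaminant": 0.0}
        cfg = cls(seed=seed,
                  transmission_prob={g: dict(shared) for g in GROUPS},
                  lps_effect_size=1.0, **overrides)
        return cfg
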