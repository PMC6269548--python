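"""Population-genomic statistics of strain populations from allele-count pileups.

Implements the SNV-filtering and diversity workflow used for
metagenome-derived strain populations: qualification of genome-sample
alignments by median coverage, breadth and genome completeness; binomial
downsampling to a target median coverage; allele-support/frequency SNV
filters; restriction to loci recovered in all compared samples; and the
intra-population nucleotide diversity pi and fixation index F_ST.

pi is the average probability that two reads drawn at random from the same
sample differ at a site (0 <= pi < 1).  F_ST between two samples mapped to
the same genome is one minus the mean intra-population diversity divided by
the between-population diversity, all three averaged over the same common
locus set.  Two estimator modes are provided: ``plugin`` draws read pairs
with replacement (allele-frequency form, F_ST of a sample with itself is
exactly 0) and ``unbiased`` draws without replacement (pair-count form).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

ALLELES = "ACGT"


class EmptyIntersectionError(ValueError):
    """Raised when compared samples share no covered locus."""


@dataclass
class Pileup:
    """Per-position allele counts of one genome in one sample.

    ``counts`` has shape (genome_length, 4) over alleles A, C, G, T.
    Positions with total depth 0 are uncovered (they define breadth).
    """

    genome_id: str
    sample_id: str
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2 or self.counts.shape[1] != 4:
            raise ValueError("counts must have shape (n_positions, 4)")
        if (self.counts < 0).any():
            raise ValueError("allele counts must be >= 0")

    @property
    def length(self) -> int:
        return self.counts.shape[0]

    @property
    def depth(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def covered_positions(self) -> np.ndarray:
        return np.nonzero(self.depth > 0)[0]

    def median_depth(self) -> float:
        """Median depth over covered positions (0 if nothing is covered)."""
        d = self.depth
        d = d[d > 0]
        return float(np.median(d)) if d.size else 0.0

    def breadth(self) -> float:
        return float((self.depth > 0).mean()) if self.length else 0.0


@dataclass
class CoverageSummary:
    genome_id: str
    sample_id: str
    median_depth: float
    breadth: float
    completeness: float

    @classmethod
    def from_pileup(cls, pileup: Pileup, completeness: float) -> "CoverageSummary":
        return cls(pileup.genome_id, pileup.sample_id,
                   pileup.median_depth(), pileup.breadth(), completeness)


@dataclass
class VariantCall:
    """A polymorphic column: alleles passing the support and frequency filters."""

    genome_id: str
    position: int
    alleles: dict[str, tuple[int, float]]  # allele -> (count, frequency)

    @property
    def depth(self) -> int:
        return sum(c for c, _ in self.alleles.values())


@dataclass
class PopGenResult:
    """One pi or F_ST value with its provenance."""

    genome_id: str
    statistic: str            # "pi" or "fst"
    samples: tuple[str, ...]  # one sample for pi, two for fst
    value: float
    n_loci: int
    mode: str


def qualify_genome_sample(summary: CoverageSummary,
                          min_median_depth: float = 20.0,
                          min_breadth: float = 0.40,
                          min_completeness: float = 0.65) -> tuple[bool, list[str]]:
    """Decide whether a genome-sample alignment enters the analysis.

    Included iff median depth >= 20X and breadth >= 40% and genome
    completeness > 65%; all failing gates are reported.
    """
    reasons = []
    if summary.median_depth < min_median_depth:
        reasons.append("coverage")
    if summary.breadth < min_breadth:
        reasons.append("breadth")
    if not summary.completeness > min_completeness:
        reasons.append("completeness")
    return (not reasons, reasons)


def downsample_to_median(pileup: Pileup, target: float = 20.0, seed=None) -> Pileup:
    """Thin allele counts binomially so the median depth lands near ``target``.

    Each count is thinned with probability target/median (one binomial draw
    per allele per column).  Pileups already at or below the target median
    are returned unchanged; columns thinned to depth 0 become uncovered.
    """
    if target <= 0:
        raise ValueError("target median coverage must be > 0")
    median = pileup.median_depth()
    if median <= target:
        return pileup
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p = target / median
    thinned = rng.binomial(pileup.counts.astype(np.int64), p)
    return Pileup(pileup.genome_id, pileup.sample_id, thinned.astype(pileup.counts.dtype))


def call_snvs(pileup: Pileup, min_support: int = 4, min_af: float = 0.01,
              positions: Sequence[int] | None = None) -> list[VariantCall]:
    """Call SNVs: non-major alleles with count >= 4 reads and frequency >= 1%.

    Both thresholds are inclusive.  Columns where no minor allele passes are
    monomorphic and not returned.
    """
    counts = pileup.counts
    pos = np.asarray(positions) if positions is not None else np.nonzero(counts.sum(1) > 0)[0]
    sub = counts[pos].astype(np.int64)
    depth = sub.sum(1)
    major = sub.argmax(1)  # ties resolved to the lexicographically first allele
    minor_mask = sub.copy()
    minor_mask[np.arange(len(pos)), major] = 0
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = sub / depth[:, None]
    passing = (minor_mask >= min_support) & (freq >= min_af)
    rows = np.nonzero(passing.any(1))[0]
    calls = []
    for r in rows:
        keep = passing[r].copy()
        keep[major[r]] = True  # the major allele always accompanies the call
        alleles = {ALLELES[a]: (int(sub[r, a]), float(sub[r, a] / depth[r]))
                   for a in np.nonzero(keep)[0]}
        calls.append(VariantCall(pileup.genome_id, int(pos[r]), alleles))
    return calls


def filter_pileup(pileup: Pileup, min_support: int = 4, min_af: float = 0.01) -> Pileup:
    """Zero out minor alleles failing the SNV filters, keeping major alleles.

    The result has the same coverage footprint; sub-threshold minor-allele
    reads are dropped, so downstream diversity treats those columns as
    monomorphic.
    """
    counts = pileup.counts.astype(np.int64)
    depth = counts.sum(1)
    major = counts.argmax(1)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(depth[:, None] > 0, counts / np.maximum(depth, 1)[:, None], 0.0)
    keep = (counts >= min_support) & (freq >= min_af)
    keep[np.arange(len(counts)), major] = True
    filtered = np.where(keep, counts, 0)
    filtered[depth == 0] = 0
    return Pileup(pileup.genome_id, pileup.sample_id, filtered.astype(pileup.counts.dtype))


def intersect_loci(pileups: Iterable[Pileup]) -> np.ndarray:
    """Positions covered (depth >= 1) in every sample mapped to the genome."""
    pileups = list(pileups)
    if len(pileups) < 2:
        raise ValueError("need at least two pileups to intersect loci")
    mask = pileups[0].depth > 0
    for p in pileups[1:]:
        if p.length != pileups[0].length:
            raise ValueError("pileups must cover the same genome length")
        mask &= p.depth > 0
    loci = np.nonzero(mask)[0]
    if loci.size == 0:
        raise EmptyIntersectionError(
            f"no common loci among samples {[p.sample_id for p in pileups]}")
    return loci


def _per_locus_pi(counts: np.ndarray, mode: str) -> tuple[np.ndarray, np.ndarray]:
    """Per-locus diversity and a validity mask (loci usable under ``mode``)."""
    counts = counts.astype(np.float64)
    depth = counts.sum(1)
    if mode == "plugin":
        valid = depth >= 1
        with np.errstate(invalid="ignore", divide="ignore"):
            f = counts / depth[:, None]
        pi = 1.0 - np.nansum(f * f, axis=1)
    elif mode == "unbiased":
        valid = depth >= 2
        num = depth * depth - (counts * counts).sum(1)
        with np.errstate(invalid="ignore", divide="ignore"):
            pi = num / (depth * (depth - 1.0))
    else:
        raise ValueError(f"unknown estimator mode {mode!r}")
    return pi, valid


def compute_pi(pileup: Pileup, loci: Sequence[int], mode: str = "plugin") -> float:
    """Mean per-site nucleotide diversity over the given loci.

    Monomorphic loci contribute 0; in ``unbiased`` mode loci with depth < 2
    are excluded from the average with a warning.
    """
    loci = np.asarray(loci)
    if loci.size == 0:
        raise ValueError("empty locus set")
    pi, valid = _per_locus_pi(pileup.counts[loci], mode)
    if not valid.all():
        warnings.warn(f"{(~valid).sum()} loci with insufficient depth excluded from pi "
                      f"({pileup.genome_id}/{pileup.sample_id}, mode={mode})")
    if not valid.any():
        return float("nan")
    return float(pi[valid].mean())


def compute_fst(pileup_1: Pileup, pileup_2: Pileup, loci: Sequence[int],
                mode: str = "plugin") -> float:
    """Fixation index between two samples over a common locus set.

    F_ST = 1 - mean(pi_1, pi_2) / pi_between, with pi_between the per-locus
    probability that reads drawn from the two samples differ
    (1 - sum_a f1_a * f2_a), and all three quantities averaged over the same
    loci.  Returns NaN (undefined) when pi_between is 0 over every locus.
    """
    if pileup_1.genome_id != pileup_2.genome_id:
        raise ValueError("F_ST compares two samples mapped to the same genome")
    loci = np.asarray(loci)
    if loci.size == 0:
        raise ValueError("empty locus set")
    c1 = pileup_1.counts[loci].astype(np.float64)
    c2 = pileup_2.counts[loci].astype(np.float64)
    d1, d2 = c1.sum(1), c2.sum(1)
    pi1, valid1 = _per_locus_pi(pileup_1.counts[loci], mode)
    pi2, valid2 = _per_locus_pi(pileup_2.counts[loci], mode)
    valid = valid1 & valid2 & (d1 >= 1) & (d2 >= 1)
    if not valid.any():
        return float("nan")
    if not valid.all():
        warnings.warn(f"{(~valid).sum()} loci excluded from F_ST (insufficient depth)")
    with np.errstate(invalid="ignore", divide="ignore"):
        f1 = c1 / d1[:, None]
        f2 = c2 / d2[:, None]
    between = 1.0 - (f1 * f2).sum(1)
    pi_between = float(between[valid].mean())
    if pi_between == 0.0:
        logger.info("F_ST undefined (no between-sample diversity) for %s: %s vs %s",
                    pileup_1.genome_id, pileup_1.sample_id, pileup_2.sample_id)
        return float("nan")
    intra = 0.5 * (float(pi1[valid].mean()) + float(pi2[valid].mean()))
    return 1.0 - intra / pi_between
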