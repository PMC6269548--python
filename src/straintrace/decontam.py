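"""Removal of artefactual sequences from low-biomass metagenomes.

Low-biomass samples (early-life stool, vaginal swabs) are prone to
artefactual DNA introduced during extraction and library preparation.  The
procedure implemented here combines two in-silico stages against a
negative-control sample sequenced alongside the cohort:

1. *screening* - study-sample contigs whose k-mer content is essentially
   contained in the control contigs are removed directly;
2. *joint binning* - control contigs are embedded together with each
   sample's contigs in tetranucleotide space and clustered with DBSCAN;
   every small bin (total length < 10 Mbp) holding more than 0.01% of the
   control sample's total contig length is flagged as a reconstructed
   artefact genome and its sample contigs are removed.

Both thresholds of the flagging rule are strict inequalities.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import DBSCAN
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

logger = logging.getLogger(__name__)


@dataclass
class Contig:
    contig_id: str
    sample_id: str
    sequence: str

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise ValueError(f"contig {self.contig_id}: empty sequence")
        self._codes: np.ndarray | None = None

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def codes(self) -> np.ndarray:
        """Base codes (A=0..T=3), computed once and cached."""
        if self._codes is None:
            from .simulate.sequences import encode_sequence

            self._codes = encode_sequence(self.sequence)
        return self._codes


@dataclass
class ContigBin:
    """A DBSCAN cluster of contigs with control-content accounting."""

    bin_id: str
    members: list[str]
    total_length: int
    control_length: int

    def __post_init__(self) -> None:
        if self.control_length > self.total_length:
            raise ValueError("control_length cannot exceed total_length")


# --------------------------------------------------------------- k-mer screen

def canonical_kmers(sequence: str | np.ndarray, k: int) -> np.ndarray:
    """Distinct canonical k-mers of a sequence, encoded as base-4 int64 codes.

    The canonical form of a k-mer is the numeric minimum of the k-mer and
    its reverse complement; k is capped at 31 so codes fit in 63 bits.
    ``sequence`` may be a string or a pre-encoded base-code array.
    """
    from .simulate.sequences import encode_sequence

    if k > 31:
        raise ValueError("k must be <= 31 for 63-bit k-mer codes")
    codes = (encode_sequence(sequence) if isinstance(sequence, str)
             else np.asarray(sequence, dtype=np.uint8)).astype(np.int64)
    if codes.size < k:
        return np.empty(0, dtype=np.int64)
    powers = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    fwd = np.lib.stride_tricks.sliding_window_view(codes, k) @ powers
    rc_seq = (3 - codes)[::-1]
    rev = (np.lib.stride_tricks.sliding_window_view(rc_seq, k) @ powers)[::-1]
    canon = np.minimum(fwd, rev)
    canon.sort()  # sort + adjacent-diff dedupe is faster than hashing here
    return canon[np.concatenate(([True], canon[1:] != canon[:-1]))]


_HASH_MULT = np.uint64(0x9E3779B97F4A7C15)
_MASK_BITS = 22


class KmerIndex:
    """Sorted canonical k-mer codes plus a hash-mask prefilter.

    Membership queries first consult a 2^22-bit occupancy mask (false
    positives possible, never false negatives) and fall back to binary
    search only for candidate hits, so querying contigs that share nothing
    with the index is nearly free.
    """

    def __init__(self, codes: np.ndarray):
        self.codes = np.asarray(codes, dtype=np.int64)
        self.mask = np.zeros(1 << _MASK_BITS, dtype=bool)
        if self.codes.size:
            self.mask[self._hash(self.codes)] = True

    @staticmethod
    def _hash(codes: np.ndarray) -> np.ndarray:
        h = codes.astype(np.uint64) * _HASH_MULT
        return (h >> np.uint64(64 - _MASK_BITS)).astype(np.int64)

    def count_members(self, query: np.ndarray) -> int:
        """Number of query codes present in the index (query need not be sorted)."""
        if self.codes.size == 0 or query.size == 0:
            return 0
        cand = query[self.mask[self._hash(query)]]
        if cand.size == 0:
            return 0
        pos = np.searchsorted(self.codes, cand)
        pos[pos == self.codes.size] = 0
        return int((self.codes[pos] == cand).sum())


def control_kmer_index(control_contigs: list[Contig], k: int = 31) -> KmerIndex:
    """Canonical k-mer index of the control sample (reusable across study
    samples)."""
    parts = [canonical_kmers(c.codes, k) for c in control_contigs
             if c.length >= k]
    if not parts:
        return KmerIndex(np.empty(0, dtype=np.int64))
    merged = np.concatenate(parts)
    merged.sort()
    return KmerIndex(merged[np.concatenate(([True], merged[1:] != merged[:-1]))])


def screen_against_control(sample_contigs: list[Contig],
                           control_contigs: list[Contig] | KmerIndex,
                           k: int = 31, min_containment: float = 0.9
                           ) -> tuple[set[str], set[str]]:
    """Remove sample contigs whose canonical k-mers are contained in the control.

    A contig is removed iff the fraction of its canonical k-mers found in the
    control k-mer set is >= ``min_containment``.  ``control_contigs`` may be a
    precomputed :func:`control_kmer_index`.  Contigs shorter than ``k``
    cannot be assessed and are kept with a warning.

    Returns (removed_ids, kept_ids).
    """
    if k < 11:
        raise ValueError("k must be >= 11")
    if isinstance(control_contigs, KmerIndex):
        index = control_contigs
    else:
        if not control_contigs:
            raise ValueError("control contig set must be non-empty")
        index = control_kmer_index(control_contigs, k)
    if not sample_contigs:
        raise ValueError("sample contig set must be non-empty")
    removed, kept = set(), set()
    for c in sample_contigs:
        if c.length < k:
            logger.warning("contig %s shorter than k=%d; kept unscreened", c.contig_id, k)
            kept.add(c.contig_id)
            continue
        kmers = canonical_kmers(c.codes, k)
        containment = index.count_members(kmers) / kmers.size
        (removed if containment >= min_containment else kept).add(c.contig_id)
    return removed, kept


# ------------------------------------------------------------------ embedding

def _tetra_maps() -> tuple[np.ndarray, int]:
    """Map each of the 256 tetramer codes to its canonical (rev-comp collapsed) column."""
    canon = np.empty(256, dtype=np.int64)
    for code in range(256):
        b = [(code >> s) & 3 for s in (6, 4, 2, 0)]
        rc = 0
        for x in b:  # reverse complement: complement (3-x) in reverse order
            rc = rc * 4 + (3 - x)
        canon[code] = min(code, rc)
    uniq = np.unique(canon)
    col = np.full(256, -1, dtype=np.int64)
    col[uniq] = np.arange(uniq.size)
    return col[canon], uniq.size


_TETRA_COL, N_TETRA = _tetra_maps()  # 136 canonical tetranucleotides


def tetranucleotide_frequencies(contigs: list[Contig]) -> np.ndarray:
    """Canonical tetranucleotide counts, one row per contig (136 columns)."""
    rows = np.zeros((len(contigs), N_TETRA), dtype=np.float64)
    for i, c in enumerate(contigs):
        codes = c.codes.astype(np.int64)
        if codes.size < 4:
            continue
        kmers = codes[:-3] * 64 + codes[1:-2] * 16 + codes[2:-1] * 4 + codes[3:]
        rows[i] = np.bincount(_TETRA_COL[kmers], minlength=N_TETRA)
    return rows


def embed_contigs(contigs: list[Contig], pseudocount: float = 1.0,
                  method: str = "pca", seed: int | None = None) -> pd.DataFrame:
    """Project contigs to 2-D composition space.

    Features are canonical tetranucleotide frequencies, centred-log-ratio
    transformed with ``pseudocount``.  The default method is PCA with a fixed
    sign convention (each component is flipped so its largest-magnitude
    loading is positive), making the embedding deterministic; ``method="sne"``
    selects a seeded stochastic-neighbour (t-SNE) embedding instead.

    Returns a DataFrame indexed by contig_id with columns x, y.
    """
    if len(contigs) < 3:
        raise ValueError("need at least 3 contigs to embed")
    counts = tetranucleotide_frequencies(contigs)
    comp = counts + pseudocount
    comp = comp / comp.sum(axis=1, keepdims=True)
    logc = np.log(comp)
    clr = logc - logc.mean(axis=1, keepdims=True)
    ids = [c.contig_id for c in contigs]
    if np.allclose(clr.var(axis=0).sum(), 0.0):
        logger.warning("all contigs have identical composition; zero-variance embedding")
        return pd.DataFrame(np.zeros((len(ids), 2)), index=ids, columns=["x", "y"])
    if method == "pca":
        pca = PCA(n_components=2, svd_solver="full")
        coords = pca.fit_transform(clr)
        for j in range(2):
            load = pca.components_[j]
            if load[np.argmax(np.abs(load))] < 0:
                coords[:, j] = -coords[:, j]
    elif method == "sne":
        from sklearn.manifold import TSNE

        perplexity = min(30.0, max(2.0, (len(contigs) - 1) / 3))
        coords = TSNE(n_components=2, random_state=seed,
                      perplexity=perplexity, init="pca").fit_transform(clr)
    else:
        raise ValueError(f"unknown embedding method {method!r}")
    return pd.DataFrame(coords, index=ids, columns=["x", "y"])


# -------------------------------------------------------------------- binning

def dbscan_eps_heuristic(coords: np.ndarray, n_neighbors: int = 4,
                         percentile: float = 95.0) -> float:
    """Default DBSCAN radius: the 95th percentile of 4-nearest-neighbour distances."""
    k = min(n_neighbors + 1, len(coords))
    nn = NearestNeighbors(n_neighbors=k).fit(coords)
    dist, _ = nn.kneighbors(coords)
    eps = float(np.percentile(dist[:, -1], percentile))
    return eps if eps > 0 else 1e-9


def joint_bin(embedding: pd.DataFrame, contigs: list[Contig],
              control_sample_id: str, eps: float | None = None,
              min_points: int = 5) -> tuple[list[ContigBin], set[str]]:
    """Density-cluster the joint (sample + control) embedding into bins.

    Returns the bins (each carrying total length and the length contributed
    by control-sample contigs) and the set of noise contig ids.
    """
    if embedding.empty:
        raise ValueError("embedding is empty")
    if eps is None:
        eps = dbscan_eps_heuristic(embedding.values)
        logger.info("DBSCAN eps heuristic: %.4g", eps)
    if eps <= 0:
        raise ValueError("eps must be > 0")
    labels = DBSCAN(eps=eps, min_samples=min_points).fit_predict(embedding.values)
    by_id = {c.contig_id: c for c in contigs}
    bins: list[ContigBin] = []
    noise: set[str] = set()
    for lab in sorted(set(labels)):
        ids = [cid for cid, l in zip(embedding.index, labels) if l == lab]
        if lab == -1:
            noise.update(ids)
            continue
        total = sum(by_id[i].length for i in ids)
        control = sum(by_id[i].length for i in ids
                      if by_id[i].sample_id == control_sample_id)
        bins.append(ContigBin(f"bin{lab:03d}", ids, total, control))
    return bins, noise


def flag_artefact_bins(bins: list[ContigBin], control_total_length: int,
                       max_bin_length: int = 10_000_000,
                       min_control_fraction: float = 1e-4) -> set[str]:
    """Flag putative artefact genomes among joint bins.

    A bin is flagged iff its total length is strictly below 10 Mbp and its
    control content exceeds 0.01% of the control sample's total contig
    length (both inequalities strict).
    """
    if control_total_length <= 0:
        raise ValueError("control_total_length must be > 0")
    flagged = set()
    for b in bins:
        frac = b.control_length / control_total_length
        if b.total_length < max_bin_length and frac > min_control_fraction:
            flagged.add(b.bin_id)
    return flagged


def apply_decontamination(sample_contigs: list[Contig], bins: list[ContigBin],
                          flagged_bin_ids: set[str], screened_ids: set[str]
                          ) -> tuple[list[Contig], pd.DataFrame]:
    """Remove screened contigs and members of flagged bins from a sample.

    Returns the curated contig list and a removal report (contig_id,
    sample_id, reason in {screen, bin}, bin_id).  A contig caught by both
    stages is reported once with reason "screen" (the first stage wins).
    """
    bin_of = {}
    for b in bins:
        if b.bin_id in flagged_bin_ids:
            for cid in b.members:
                bin_of[cid] = b.bin_id
    curated, rows = [], []
    for c in sample_contigs:
        if c.contig_id in screened_ids:
            rows.append((c.contig_id, c.sample_id, "screen", ""))
        elif c.contig_id in bin_of:
            rows.append((c.contig_id, c.sample_id, "bin", bin_of[c.contig_id]))
        else:
            curated.append(c)
    report = pd.DataFrame(rows, columns=["contig_id", "sample_id", "reason", "bin_id"])
    return curated, report


def decontaminate_sample(sample_contigs: list[Contig], control_contigs: list[Contig],
                         k: int = 31, min_containment: float = 0.9,
                         eps: float | None = None, min_points: int = 5,
                         rrna_exclusion: set[str] | None = None,
                         control_kmers: KmerIndex | None = None
                         ) -> tuple[list[Contig], pd.DataFrame]:
    """Full two-stage decontamination of one study sample against the control.

    ``rrna_exclusion`` is a hook for real data: contig ids listed there are
    excluded from binning (rRNA-carrying contigs confound composition-based
    clustering); synthetic contigs carry no rRNA so it defaults to empty.
    ``control_kmers`` may hold a precomputed :func:`control_kmer_index` to
    amortise the screen across samples.
    """
    control_sample_id = control_contigs[0].sample_id
    if control_kmers is None:
        control_kmers = control_kmer_index(control_contigs, k)
    screened, kept = screen_against_control(sample_contigs, control_kmers,
                                            k=k, min_containment=min_containment)
    survivors = [c for c in sample_contigs if c.contig_id in kept]
    excl = rrna_exclusion or set()
    joint = [c for c in survivors + control_contigs if c.contig_id not in excl]
    if len(joint) >= 3:
        embedding = embed_contigs(joint)
        bins, _ = joint_bin(embedding, joint, control_sample_id,
                            eps=eps, min_points=min_points)
        control_total = sum(c.length for c in control_contigs)
        flagged = flag_artefact_bins(bins, control_total)
    else:
        bins, flagged = [], set()
    return apply_decontamination(sample_contigs, bins, flagged, screened)
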