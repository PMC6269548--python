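"""Per-sample genome reconstruction and cross-sample linking via marker genes.

Curated contigs are clustered into genome bins using composition plus
coverage; bins are linked across the samples of a mother-neonate pair by
clustering the amino-acid sequences of 35 universal single-copy marker
families at 97.5% identity and counting, for every bin pair, the marker
clusters in which both are represented.  Communities of the resulting
weighted co-occurrence graph (greedy modularity maximisation) are the
putative cross-sample genomes.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import edlib
import networkx as nx
import numpy as np
import pandas as pd

from .decontam import Contig, dbscan_eps_heuristic, embed_contigs

logger = logging.getLogger(__name__)

N_MARKER_FAMILIES = 35

_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")


@dataclass
class GenomeBin:
    """A within-sample genome reconstruction."""

    bin_id: str
    sample_id: str
    members: list[str]
    total_length: int
    completeness: float = float("nan")
    marker_hits: dict[int, list[str]] = field(default_factory=dict)  # family -> marker ids
    inferred_label: str | None = None  # evaluation only; attached externally


@dataclass(frozen=True)
class MarkerGene:
    """One predicted marker-protein sequence from one sample."""

    marker_id: str
    family_id: int
    sequence: str
    sample_id: str
    individual_id: str | None = None
    contig_id: str | None = None
    source_bin: str | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"marker {self.marker_id}: empty sequence")


@dataclass
class MarkerCluster:
    cluster_id: str
    representative: MarkerGene
    members: list[MarkerGene]


def alignment_identity(a: str, b: str) -> float:
    """Global-alignment identity: matches / alignment length.

    Match scores 1, mismatch 0, and gap columns count as mismatches (they
    enter the alignment length but not the match count).
    """
    if a == b:
        return 1.0
    res = edlib.align(a, b, mode="NW", task="path")
    matches = align_len = 0
    for num, op in _CIGAR_RE.findall(res["cigar"]):
        n = int(num)
        align_len += n
        if op == "=":
            matches += n
    return matches / align_len


def identity_at_least(a: str, b: str, threshold: float) -> bool:
    """Decide ``alignment_identity(a, b) >= threshold`` cheaply.

    Uses a banded edit-distance computation with alignment-length bounds
    (max(la,lb) <= alignment length <= min(la,lb) + edits); the full
    alignment is only produced when the bounds cannot decide.
    """
    if a == b:
        return True
    la, lb = len(a), len(b)
    lo, hi = min(la, lb), max(la, lb)
    if lo / hi < threshold:
        return False
    k_reject = int(lo * (1 - threshold) / threshold) + 1
    res = edlib.align(a, b, mode="NW", task="distance", k=k_reject)
    e = res["editDistance"]
    if e == -1:
        return False
    if (hi - e) / hi >= threshold:
        return True
    if lo / (lo + e) < threshold:
        return False
    return alignment_identity(a, b) >= threshold


def bin_sample(contigs: list[Contig], coverage: dict[str, float],
               eps: float | None = None, min_points: int = 5,
               min_bin_length: int = 100_000) -> list[GenomeBin]:
    """Cluster one sample's curated contigs into genome bins.

    The feature space is the 2-D composition embedding joined with
    log-coverage, each axis standardised; DBSCAN separates genomes that
    share composition but differ in abundance.  Bins below
    ``min_bin_length`` total length are discarded as fragments.
    """
    if not contigs:
        return []
    if len(contigs) < 3:
        return []
    emb = embed_contigs(contigs)
    cov = np.array([np.log10(max(coverage.get(c.contig_id, 1e-3), 1e-3)) for c in contigs])
    feats = np.column_stack([emb.values, cov])
    std = feats.std(axis=0)
    std[std == 0] = 1.0
    feats = (feats - feats.mean(axis=0)) / std
    if eps is None:
        eps = dbscan_eps_heuristic(feats)
    from sklearn.cluster import DBSCAN

    labels = DBSCAN(eps=eps, min_samples=min_points).fit_predict(feats)
    by_id = {c.contig_id: c for c in contigs}
    sample_id = contigs[0].sample_id
    bins = []
    for lab in sorted(set(labels) - {-1}):
        ids = [c.contig_id for c, l in zip(contigs, labels) if l == lab]
        total = sum(by_id[i].length for i in ids)
        if total < min_bin_length:
            continue
        bins.append(GenomeBin(f"{sample_id}.bin{lab:03d}", sample_id, ids, total))
    return bins


def attach_markers(bins: list[GenomeBin], markers: list[MarkerGene]) -> list[MarkerGene]:
    """Assign markers to the bins whose contigs carry them.

    Returns new MarkerGene records tagged with their source bin; markers on
    unbinned contigs are returned untagged.
    """
    bin_of: dict[str, GenomeBin] = {}
    for b in bins:
        for cid in b.members:
            bin_of[cid] = b
    out = []
    for m in markers:
        b = bin_of.get(m.contig_id)
        if b is not None:
            b.marker_hits.setdefault(m.family_id, []).append(m.marker_id)
            m = MarkerGene(m.marker_id, m.family_id, m.sequence, m.sample_id,
                           m.individual_id, m.contig_id, source_bin=b.bin_id)
        out.append(m)
    return out


def estimate_completeness(genome_bin: GenomeBin,
                          n_families: int = N_MARKER_FAMILIES) -> float:
    """Fraction of the marker families with at least one hit in the bin."""
    frac = len(genome_bin.marker_hits) / n_families
    genome_bin.completeness = frac
    return frac


def cluster_marker_proteins(markers: list[MarkerGene],
                            identity_threshold: float = 0.975) -> list[MarkerCluster]:
    """Greedy incremental clustering of marker proteins by global identity.

    Sequences are processed by decreasing length (ties broken by marker id);
    each joins the first existing cluster whose representative it matches at
    identity >= threshold (inclusive), else founds a new cluster.  This is
    the CD-HIT-style greedy scheme with exact global identities in place of
    word heuristics.
    """
    ordered = sorted(markers, key=lambda m: (-len(m.sequence), m.marker_id))
    clusters: list[MarkerCluster] = []
    for m in ordered:
        placed = False
        for cl in clusters:
            if identity_at_least(m.sequence, cl.representative.sequence,
                                 identity_threshold):
                cl.members.append(m)
                placed = True
                break
        if not placed:
            clusters.append(MarkerCluster(f"mc{len(clusters):05d}", m, [m]))
    return clusters


def build_link_graph(bins: list[GenomeBin], clusters: list[MarkerCluster]) -> nx.Graph:
    """Weighted co-occurrence graph over genome bins.

    Edge weight between two bins is the number of marker clusters containing
    sequences from both; nodes are all bin ids (bins without shared clusters
    stay isolated).
    """
    graph = nx.Graph()
    graph.add_nodes_from(b.bin_id for b in bins)
    for cl in clusters:
        present = sorted({m.source_bin for m in cl.members if m.source_bin is not None})
        for i, b1 in enumerate(present):
            for b2 in present[i + 1:]:
                if graph.has_edge(b1, b2):
                    graph[b1][b2]["weight"] += 1
                else:
                    graph.add_edge(b1, b2, weight=1)
    return graph


def detect_communities(graph: nx.Graph) -> list[set[str]]:
    """Greedy modularity communities of the weighted link graph.

    Each community is one putative cross-sample genome; isolated nodes form
    singleton communities.  The returned communities partition the node set.
    """
    if graph.number_of_nodes() == 0:
        return []
    if graph.number_of_edges() == 0:
        return [{n} for n in sorted(graph.nodes)]
    comms = nx.community.greedy_modularity_communities(graph, weight="weight")
    return [set(c) for c in comms]


def ambiguous_communities(communities: list[set[str]],
                          bins: list[GenomeBin]) -> pd.DataFrame:
    """Report communities containing more than one bin from a single sample.

    These are the cases a human would have inspected by hand: a genome
    should be reconstructed at most once per sample, so multiple same-sample
    bins in one community indicate either an over-split genome or a chimeric
    link.
    """
    sample_of = {b.bin_id: b.sample_id for b in bins}
    rows = []
    for i, comm in enumerate(communities):
        per_sample: dict[str, list[str]] = {}
        for bid in comm:
            per_sample.setdefault(sample_of.get(bid, "?"), []).append(bid)
        for sample, ids in per_sample.items():
            if len(ids) > 1:
                rows.append((i, sample, ",".join(sorted(ids))))
    return pd.DataFrame(rows, columns=["community", "sample_id", "bins"])
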