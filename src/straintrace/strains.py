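"""Strain-level transmission calls from marker phylogenies.

For every clade (a genome-level group of marker sequences recovered across
samples), a neighbour-joining tree is built from pairwise marker
p-distances and a neonate is considered to share the maternal strain iff
the cophenetic distance between its markers and the mother's markers is
strictly smaller than the distance to the markers of any other individual.
Ties are conservative (not shared); the margin between the nearest other
individual and the mother is exported so users can threshold the strength
of evidence themselves.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import edlib
import networkx as nx
import numpy as np
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj

from .linking import MarkerGene, _CIGAR_RE, cluster_marker_proteins

logger = logging.getLogger(__name__)


@dataclass
class SharingCall:
    """A mother-to-neonate strain-sharing decision for one clade."""

    pair_id: str
    clade_id: str
    shared: bool
    evidence: str  # "genome_based" or "read_based"
    margin: float  # (min distance to any other individual) - (distance to mother)
    mother_distance: float
    min_other_distance: float


def marker_distance(seq_a: str, seq_b: str) -> float:
    """p-distance between two marker sequences.

    Equal-length inputs are treated as aligned; unequal-length inputs are
    globally aligned first.  Gap columns are excluded from both the
    numerator and the denominator; the distance is the fraction of
    ungapped aligned positions that differ.
    """
    if len(seq_a) == len(seq_b):
        pairs = [(x, y) for x, y in zip(seq_a, seq_b) if x != "-" and y != "-"]
        if not pairs:
            raise ValueError("no overlapping ungapped positions")
        return sum(x != y for x, y in pairs) / len(pairs)
    res = edlib.align(seq_a, seq_b, mode="NW", task="path")
    matches = mismatches = 0
    for num, op in _CIGAR_RE.findall(res["cigar"]):
        if op == "=":
            matches += int(num)
        elif op == "X":
            mismatches += int(num)
    if matches + mismatches == 0:
        raise ValueError("no overlapping ungapped positions")
    return mismatches / (matches + mismatches)


def build_nj_tree(matrix: DistanceMatrix) -> TreeNode:
    """Neighbour-joining tree from a distance matrix.

    Negative branch-length estimates are clamped to zero; on additive
    matrices NJ reproduces the generating tree exactly.
    """
    if not isinstance(matrix, DistanceMatrix):
        matrix = DistanceMatrix(np.asarray(matrix[0]), matrix[1])
    if matrix.shape[0] < 3:
        raise ValueError("neighbour joining needs at least 3 labels")
    return nj(matrix, neg_as_zero=True)


def cophenetic_matrix(tree: TreeNode) -> DistanceMatrix:
    """Leaf-to-leaf path-length (cophenetic) distances of a tree."""
    return tree.tip_tip_distances()


def call_strain_sharing(cophenetic: DistanceMatrix,
                        neonate_labels: Sequence[str] | str,
                        mother_labels: Sequence[str] | str,
                        other_individual_labels: Mapping[str, Sequence[str]],
                        pair_id: str = "", clade_id: str = "",
                        evidence: str = "read_based") -> SharingCall:
    """Apply the nearest-individual strain-sharing criterion.

    ``other_individual_labels`` maps every competing individual to its leaf
    labels; an individual with several samples is represented by its
    minimum distance.  Sharing requires the mother distance to be strictly
    below the minimum over all other individuals; exact ties are not shared.
    """
    if isinstance(neonate_labels, str):
        neonate_labels = [neonate_labels]
    if isinstance(mother_labels, str):
        mother_labels = [mother_labels]
    others = {ind: list(labels) for ind, labels in other_individual_labels.items() if labels}
    if not others:
        raise ValueError("sharing criterion undefined without other individuals")

    def dmin(labels_a, labels_b) -> float:
        return min(float(cophenetic[a, b]) for a in labels_a for b in labels_b)

    d_mother = dmin(neonate_labels, mother_labels)
    d_other = min(dmin(neonate_labels, labels) for labels in others.values())
    margin = d_other - d_mother
    return SharingCall(pair_id=pair_id, clade_id=clade_id,
                       shared=d_mother < d_other, evidence=evidence,
                       margin=margin, mother_distance=d_mother,
                       min_other_distance=d_other)


# ---------------------------------------------------------------- clade tools

@dataclass
class Clade:
    """A genome-level group of marker clusters recovered across samples."""

    clade_id: str
    cluster_ids: list[str]
    members: list[MarkerGene]


def detect_clades(markers: list[MarkerGene], clade_identity: float = 0.90,
                  min_presence_jaccard: float = 0.95) -> list[Clade]:
    """Group marker sequences into genome-level clades without a reference.

    Markers are clustered at a coarse identity (default 90%, loose enough to
    span within-species strain divergence); per-family clusters whose
    sample-presence sets agree (Jaccard >= threshold) are merged into one
    clade by connected components, exploiting the fact that the 35
    single-copy families of one genome travel together across samples.
    Clustering runs within each marker family (sequences of different
    families never approach the identity threshold).
    """
    by_family: dict[int, list[MarkerGene]] = {}
    for m in markers:
        by_family.setdefault(m.family_id, []).append(m)
    clusters = []
    for fam in sorted(by_family):
        for cl in cluster_marker_proteins(by_family[fam],
                                          identity_threshold=clade_identity):
            cl.cluster_id = f"f{fam:02d}.{cl.cluster_id}"
            clusters.append(cl)
    presence = {cl.cluster_id: {m.sample_id for m in cl.members} for cl in clusters}
    graph = nx.Graph()
    graph.add_nodes_from(presence)
    ids = sorted(presence)
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            sa, sb = presence[a], presence[b]
            union = len(sa | sb)
            if union and len(sa & sb) / union >= min_presence_jaccard:
                graph.add_edge(a, b)
    by_id = {cl.cluster_id: cl for cl in clusters}
    clades = []
    for comp in sorted(nx.connected_components(graph), key=lambda c: sorted(c)[0]):
        cluster_ids = sorted(comp)
        members = [m for cid in cluster_ids for m in by_id[cid].members]
        clades.append(Clade(f"clade{len(clades):03d}", cluster_ids, members))
    return clades


def clade_distance_matrix(clade: Clade, entity_of) -> DistanceMatrix | None:
    """Pairwise mean marker p-distance between entities (samples or bins).

    ``entity_of`` maps a MarkerGene to an entity label (e.g. its sample id
    for read-based evidence, its bin id for genome-based evidence); markers
    mapping to ``None`` are skipped.  Each entity keeps one sequence per
    marker family (smallest marker id, deterministic) and distances average
    over the families both entities share.  Returns ``None`` when fewer than
    three entities are represented.
    """
    seqs: dict[str, dict[int, MarkerGene]] = {}
    for m in clade.members:
        ent = entity_of(m)
        if ent is None:
            continue
        bucket = seqs.setdefault(ent, {})
        if m.family_id not in bucket or m.marker_id < bucket[m.family_id].marker_id:
            bucket[m.family_id] = m
    entities = sorted(seqs)
    if len(entities) < 3:
        return None
    n = len(entities)
    dist_sum = np.zeros((n, n))
    shared = np.zeros((n, n))
    families = sorted({f for bucket in seqs.values() for f in bucket})
    index = {e: i for i, e in enumerate(entities)}
    for fam in families:
        have = [e for e in entities if fam in seqs[e]]
        if len(have) < 2:
            continue
        by_len: dict[int, list[str]] = {}
        for e in have:
            by_len.setdefault(len(seqs[e][fam].sequence), []).append(e)
        for length, group in by_len.items():
            idx = np.array([index[e] for e in group])
            arr = np.frombuffer("".join(seqs[e][fam].sequence for e in group)
                                .encode("ascii"), dtype=np.uint8).reshape(len(group), length)
            pd = (arr[:, None, :] != arr[None, :, :]).mean(axis=2)
            dist_sum[np.ix_(idx, idx)] += pd
            shared[np.ix_(idx, idx)] += 1.0
        # unequal-length pairs (possible in merged clades): align explicitly
        lengths = sorted(by_len)
        for a, b in itertools.combinations(lengths, 2):
            for ea in by_len[a]:
                for eb in by_len[b]:
                    i, j = index[ea], index[eb]
                    d = marker_distance(seqs[ea][fam].sequence, seqs[eb][fam].sequence)
                    dist_sum[i, j] += d
                    dist_sum[j, i] += d
                    shared[i, j] += 1.0
                    shared[j, i] += 1.0
    with np.errstate(invalid="ignore", divide="ignore"):
        dm = np.where(shared > 0, dist_sum / np.maximum(shared, 1), 1.0)
    np.fill_diagonal(dm, 0.0)
    dm = 0.5 * (dm + dm.T)
    return DistanceMatrix(dm, entities)
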