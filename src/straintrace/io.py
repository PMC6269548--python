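"""Readers and writers for the plain-text interchange formats.

Contigs and marker proteins travel as FASTA; allele-count pileups as TSV
(columns genome_id, pos 0-based, sample_id, A, C, G, T) or as minimal
VCF 4.2 with per-sample AD (allelic depth) and DP genotype fields; sample
metadata, gene hits, pathway maps and Gram tables as TSV.
"""

from __future__ import annotations


from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .decontam import Contig
from .linking import MarkerGene
from .popgen import ALLELES, Pileup


# ---------------------------------------------------------------------- FASTA

def write_contig_fasta(contigs: Iterable[Contig], path) -> None:
    records = [SeqRecord(Seq(c.sequence), id=c.contig_id, description="")
               for c in contigs]
    SeqIO.write(records, str(path), "fasta")


def read_contig_fasta(path, sample_id: str) -> list[Contig]:
    return [Contig(rec.id, sample_id, str(rec.seq))
            for rec in SeqIO.parse(str(path), "fasta")]


def write_marker_fasta(markers: Iterable[MarkerGene], path) -> None:
    records = [SeqRecord(Seq(m.sequence), id=m.marker_id,
                         description=f"family={m.family_id} sample={m.sample_id}")
               for m in markers]
    SeqIO.write(records, str(path), "fasta")


def read_marker_fasta(path, individual_of: Mapping[str, str] | None = None
                      ) -> list[MarkerGene]:
    """Parse marker FASTA written by :func:`write_marker_fasta`.

    ``individual_of`` optionally maps sample ids to individual ids so the
    markers come back tagged for the sharing criterion.
    """
    markers = []
    for rec in SeqIO.parse(str(path), "fasta"):
        fields = dict(kv.split("=", 1) for kv in rec.description.split()[1:]
                      if "=" in kv)
        sample = fields.get("sample", "")
        markers.append(MarkerGene(
            marker_id=rec.id, family_id=int(fields.get("family", 0)),
            sequence=str(rec.seq), sample_id=sample,
            individual_id=(individual_of or {}).get(sample),
            contig_id=rec.id.rsplit(".m", 1)[0] if ".m" in rec.id else None))
    return markers


# ----------------------------------------------------------------- pileup TSV

def write_pileup_tsv(pileups: Iterable[Pileup], path) -> None:
    """Write covered columns (depth >= 1) of the given pileups."""
    frames = []
    for p in sorted(pileups, key=lambda p: (p.genome_id, p.sample_id)):
        covered = p.covered_positions
        frame = pd.DataFrame(p.counts[covered], columns=list(ALLELES))
        frame.insert(0, "sample_id", p.sample_id)
        frame.insert(0, "pos", covered)
        frame.insert(0, "genome_id", p.genome_id)
        frames.append(frame)
    table = (pd.concat(frames, ignore_index=True) if frames
             else pd.DataFrame(columns=["genome_id", "pos", "sample_id", *ALLELES]))
    table.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_pileup_tsv(path, genome_lengths: Mapping[str, int] | None = None
                    ) -> dict[tuple[str, str], Pileup]:
    """Load pileups keyed by (genome_id, sample_id).

    Genome lengths default to the largest observed position + 1, which is
    correct whenever the final reference position is covered in some sample.
    """
    df = pd.read_csv(path, sep="\t")
    lengths = dict(genome_lengths or {})
    for gid, sub in df.groupby("genome_id"):
        lengths.setdefault(gid, int(sub["pos"].max()) + 1)
    out: dict[tuple[str, str], Pileup] = {}
    for (gid, sid), sub in df.groupby(["genome_id", "sample_id"]):
        counts = np.zeros((lengths[gid], 4), dtype=np.int64)
        counts[sub["pos"].values] = sub[list(ALLELES)].values
        out[(gid, sid)] = Pileup(gid, sid, counts)
    return out


# ------------------------------------------------------------------------ VCF

def write_vcf(pileups: Mapping[tuple[str, str], Pileup],
              reference: Mapping[str, np.ndarray], path) -> None:
    """Minimal VCF 4.2 export of polymorphic columns.

    CHROM is the genome id, POS is 1-based, REF the reference base, ALT the
    non-reference alleles observed in any sample; genotype fields carry
    AD (per-allele depth, REF first) and DP.
    """
    by_genome: dict[str, list[Pileup]] = {}
    for (gid, _), p in sorted(pileups.items()):
        by_genome.setdefault(gid, []).append(p)
    sample_ids = sorted({p.sample_id for p in pileups.values()})
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for gid, plist in sorted(by_genome.items()):
            fh.write(f"##contig=<ID={gid},length={plist[0].length}>\n")
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,'
                 'Description="Allelic depths">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Depth">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(sample_ids) + "\n")
        for gid, plist in sorted(by_genome.items()):
            ref = np.asarray(reference[gid])
            stacked = np.stack([p.counts for p in plist])  # (samples, L, 4)
            observed = (stacked > 0).any(axis=0)
            n_alleles = observed.sum(axis=1)
            ref_missing = ~observed[np.arange(ref.size), ref]
            variant_pos = np.nonzero((n_alleles > 1) | ((n_alleles > 0) & ref_missing))[0]
            present = {p.sample_id: p for p in plist}
            depths = {p.sample_id: p.depth for p in plist}
            for pos in variant_pos.tolist():
                ref_base = ALLELES[ref[pos]]
                alts = [ALLELES[a] for a in range(4)
                        if observed[pos, a] and a != ref[pos]]
                order = [ref[pos]] + [a for a in range(4)
                                      if observed[pos, a] and a != ref[pos]]
                cols = []
                for sid in sample_ids:
                    p = present.get(sid)
                    if p is None or depths[sid][pos] == 0:
                        cols.append("./.:.:.")
                        continue
                    ad = ",".join(str(int(p.counts[pos, a])) for a in order)
                    cols.append(f".:{ad}:{int(depths[sid][pos])}")
                fh.write(f"{gid}\t{pos + 1}\t.\t{ref_base}\t{','.join(alts) or '.'}"
                         f"\t.\t.\t.\tGT:AD:DP\t" + "\t".join(cols) + "\n")


def read_vcf_allele_counts(path) -> pd.DataFrame:
    """Read a minimal AD/DP VCF into a long allele-count table.

    Columns: genome_id, pos (0-based), sample_id, allele, count.  Uses pysam
    for parsing, so any spec-conforming VCF 4.2 works, not only files
    written by :func:`write_vcf`.
    """
    import pysam

    rows = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            alleles = (rec.ref,) + tuple(rec.alts or ())
            for sample, call in rec.samples.items():
                ad = call.get("AD")
                if ad is None or all(a is None for a in ad):
                    continue
                for allele, count in zip(alleles, ad):
                    rows.append((rec.chrom, rec.pos - 1, sample, allele,
                                 int(count or 0)))
    return pd.DataFrame(rows, columns=["genome_id", "pos", "sample_id",
                                       "allele", "count"])


# ------------------------------------------------------------------- metadata

def write_sample_metadata(samples, path) -> None:
    rows = [(s.sample_id, s.individual_id, s.pair_id or "", s.role, s.body_site,
             "" if s.day is None else s.day, s.group or "") for s in samples]
    pd.DataFrame(rows, columns=["sample_id", "individual_id", "pair_id", "role",
                                "body_site", "day", "group"]
                 ).to_csv(path, sep="\t", index=False)


def read_sample_metadata(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    df["day"] = df["day"].map(lambda v: int(float(v)) if v != "" else None)
    return df


def write_gene_hits(hits_by_sample: Mapping[str, list], path) -> None:
    rows = []
    for sample in sorted(hits_by_sample):
        for h in hits_by_sample[sample]:
            for ko, score in sorted(h.candidates.items()):
                rows.append((h.gene_id, sample, ko, score, h.read_count))
    pd.DataFrame(rows, columns=["gene_id", "sample_id", "ko", "bit_score",
                                "read_count"]).to_csv(path, sep="\t", index=False)


def write_pathway_map(pathway_map: Mapping[str, set], path) -> None:
    rows = [(pw, ko) for pw in sorted(pathway_map) for ko in sorted(pathway_map[pw])]
    pd.DataFrame(rows, columns=["pathway_id", "ko_id"]).to_csv(path, sep="\t",
                                                               index=False)


def read_pathway_map(path) -> dict[str, set]:
    df = pd.read_csv(path, sep="\t")
    return {pw: set(sub["ko_id"]) for pw, sub in df.groupby("pathway_id")}


def write_gram_table(gram: Mapping[str, str], path) -> None:
    pd.DataFrame(sorted(gram.items()), columns=["genus", "gram"]
                 ).to_csv(path, sep="\t", index=False)


def read_gram_table(path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df["genus"], df["gram"]))
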