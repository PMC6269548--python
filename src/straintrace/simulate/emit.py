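"""Serialize a synthetic cohort to the plain-text interchange formats."""

from __future__ import annotations

import json
from pathlib import Path

from .. import io as stio
from .cohort import SyntheticCohort


def emit_contigs(cohort: SyntheticCohort, outdir) -> dict[str, Path]:
    """Write one contig FASTA per sample (including the control).

    Contigs are substrings of their source genome's strain consensus; ids
    carry only the sample name and an arbitrary index.  Deterministic for a
    fixed cohort, so identical seeds give byte-identical files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for sample in cohort.samples:
        path = outdir / f"{sample.sample_id}.contigs.fasta"
        stio.write_contig_fasta(cohort.contigs[sample.sample_id], path)
        paths[sample.sample_id] = path
    return paths


def emit_markers(cohort: SyntheticCohort, outdir) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for sample in cohort.samples:
        path = outdir / f"{sample.sample_id}.markers.faa"
        stio.write_marker_fasta(cohort.markers[sample.sample_id], path)
        paths[sample.sample_id] = path
    return paths


def emit_pileups(cohort: SyntheticCohort, outdir, vcf: bool = True) -> dict[str, Path]:
    """Write per-genome pileup TSVs (covered columns only) and a minimal VCF.

    Column depths are Poisson around mean coverage x relative abundance and
    allele counts multinomial around the true allele frequencies; positions
    with depth 0 are omitted, which is what defines breadth downstream.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    by_genome: dict[str, list] = {}
    for (gid, _sid), pileup in sorted(cohort.pileups.items()):
        by_genome.setdefault(gid, []).append(pileup)
    paths = {}
    for gid, plist in sorted(by_genome.items()):
        path = outdir / f"{gid}.pileup.tsv"
        stio.write_pileup_tsv(plist, path)
        paths[gid] = path
    if vcf:
        vcf_path = outdir / "variants.vcf"
        stio.write_vcf(cohort.pileups,
                       {gid: g.sequence for gid, g in cohort.genomes.items()},
                       vcf_path)
        paths["vcf"] = vcf_path
    return paths


def emit_truth(cohort: SyntheticCohort, path) -> Path:
    """Ground truth as JSON (allele-frequency matrices are kept in memory only;
    per-sample true pi summarises them)."""
    truth = cohort.truth
    payload = {
        "transmitted": sorted([list(t) for t in truth.transmitted]),
        "contaminant_contigs": sorted(truth.contaminant_contigs),
        "planted_da_kos": sorted(truth.planted_da_kos),
        "gram_labels": dict(sorted(truth.gram_labels.items())),
        "true_pi": {f"{g}|{s}": v for (g, s), v in sorted(truth.true_pi.items())},
        "contig_sources": dict(sorted(truth.contig_sources.items())),
    }
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(payload, indent=1, sort_keys=True))
    return path


def emit_cohort(cohort: SyntheticCohort, outdir) -> dict[str, object]:
    """Write the full cohort: config, metadata, contigs, markers, pileups,
    gene hits, pathway map, Gram table and ground truth."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cohort.config.to_yaml(outdir / "config.yaml")
    stio.write_sample_metadata(cohort.samples, outdir / "samples.tsv")
    stio.write_gene_hits(cohort.gene_hits, outdir / "gene_hits.tsv")
    stio.write_pathway_map(cohort.pathway_map, outdir / "pathways.tsv")
    stio.write_gram_table(cohort.gram_table, outdir / "gram.tsv")
    paths = {
        "contigs": emit_contigs(cohort, outdir / "contigs"),
        "markers": emit_markers(cohort, outdir / "markers"),
        "pileups": emit_pileups(cohort, outdir / "pileups"),
        "truth": emit_truth(cohort, outdir / "truth.json"),
    }
    return paths
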