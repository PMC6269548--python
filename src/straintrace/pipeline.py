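"""End-to-end orchestration over a synthetic cohort, with evaluation.

``run_all`` executes simulate -> decontaminate -> bin/link -> strain
tracking -> population genomics -> functional analysis -> evaluation and
assembles a structured, JSON-serialisable report.  Every stage consumes
the previous stage's outputs through the same interfaces that real-data
users would feed with files, and every stochastic step derives its seed
from the run seed, so identical configurations give identical reports.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import decontam as dc
from . import functional as fn
from . import io as stio
from . import linking as lk
from . import popgen as pg
from . import strains as st
from .simulate import CohortConfig, SyntheticCohort, generate_cohort

logger = logging.getLogger(__name__)

__version__ = "0.1.0"

STAGES = ("simulate", "decontam", "binning", "linking", "strains",
          "popgen", "functional", "evaluate")


class PipelineValidationError(ValueError):
    """Invalid pipeline configuration (maps to exit code 2 in the CLI)."""


@dataclass
class PipelineConfig:
    """Run configuration: a cohort to simulate (or input paths), stage
    parameters, the run seed and the output directory."""

    cohort: CohortConfig | None = None
    input_dir: str | None = None
    outdir: str | None = None
    seed: int | None = None
    stages: tuple[str, ...] = STAGES
    decontam_params: dict = field(default_factory=dict)    # k, min_containment, eps, min_points
    binning_params: dict = field(default_factory=dict)     # eps, min_points, min_bin_length
    linking_params: dict = field(default_factory=dict)     # identity_threshold
    strains_params: dict = field(default_factory=dict)     # clade_identity, min_presence_jaccard
    popgen_params: dict = field(default_factory=dict)      # target_median, min_support, min_af, estimator
    functional_params: dict = field(default_factory=dict)  # alpha
    log_level: str = "INFO"

    def validate(self) -> None:
        if self.cohort is None and self.input_dir is None:
            raise PipelineValidationError("either a cohort configuration or an "
                                          "input directory is required")
        if self.cohort is None and self.input_dir is not None:
            if not Path(self.input_dir).exists():
                raise PipelineValidationError(f"input_dir does not exist: {self.input_dir}")
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise PipelineValidationError(f"unknown stages: {sorted(unknown)}")
        if self.cohort is not None and self.seed is not None:
            self.cohort.seed = self.seed

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        cohort = data.pop("cohort", None)
        cfg = cls(cohort=CohortConfig.from_dict(cohort) if cohort else None,
                  **data)
        return cfg


@dataclass
class EvaluationMetrics:
    task: str
    tp: int
    fp: int
    fn: int

    @property
    def precision(self) -> float:
        if self.tp + self.fp == 0:
            return 1.0 if self.fn == 0 else float("nan")
        return self.tp / (self.tp + self.fp)

    @property
    def recall(self) -> float:
        if self.tp + self.fn == 0:
            return 1.0 if self.fp == 0 else float("nan")
        return self.tp / (self.tp + self.fn)

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        if math.isnan(p) or math.isnan(r) or p + r == 0:
            return float("nan")
        return 2 * p * r / (p + r)

    def to_dict(self) -> dict:
        return {"task": self.task, "tp": self.tp, "fp": self.fp, "fn": self.fn,
                "precision": self.precision, "recall": self.recall, "f1": self.f1}


def evaluate_calls(calls: set, truth: set, task: str) -> EvaluationMetrics:
    """Set comparison of called items against ground-truth items."""
    if task not in ("decontamination", "linking", "sharing"):
        raise ValueError(f"unknown evaluation task {task!r}")
    calls, truth = set(calls), set(truth)
    return EvaluationMetrics(task, tp=len(calls & truth), fp=len(calls - truth),
                             fn=len(truth - calls))


# ------------------------------------------------------------- stage helpers

def decontaminate_cohort(cohort: SyntheticCohort, **params
                         ) -> tuple[dict[str, list], pd.DataFrame]:
    """Run the two-stage artefact removal on every study sample.

    Returns curated contigs per sample and the concatenated removal report.
    """
    control = cohort.contigs[cohort.control_sample.sample_id]
    index = dc.control_kmer_index(control, k=params.get("k", 31))
    curated: dict[str, list] = {}
    reports = []
    for sample in cohort.samples:
        if sample.role == "control":
            continue
        kept, report = dc.decontaminate_sample(
            cohort.contigs[sample.sample_id], control,
            control_kmers=index, **params)
        curated[sample.sample_id] = kept
        reports.append(report)
    report = pd.concat(reports, ignore_index=True) if reports else pd.DataFrame(
        columns=["contig_id", "sample_id", "reason", "bin_id"])
    return curated, report


def bin_cohort(cohort: SyntheticCohort, curated: dict[str, list], **params
               ) -> tuple[dict[str, list[lk.GenomeBin]], dict[str, list[lk.MarkerGene]]]:
    """Genome-bin each curated sample and attach surviving markers to bins."""
    bins_by_sample: dict[str, list[lk.GenomeBin]] = {}
    markers_by_sample: dict[str, list[lk.MarkerGene]] = {}
    for sample_id, contigs in sorted(curated.items()):
        bins = lk.bin_sample(contigs, cohort.contig_coverage, **params)
        surviving = {c.contig_id for c in contigs}
        markers = [m for m in cohort.markers[sample_id] if m.contig_id in surviving]
        markers = lk.attach_markers(bins, markers)
        for b in bins:
            lk.estimate_completeness(b)
            b.inferred_label = _majority_genome(b.members, cohort)
        bins_by_sample[sample_id] = bins
        markers_by_sample[sample_id] = markers
    return bins_by_sample, markers_by_sample


def _majority_genome(contig_ids, cohort: SyntheticCohort) -> str | None:
    """Length-weighted majority source genome of a contig set (evaluation only)."""
    weights: dict[str, int] = {}
    for cid in contig_ids:
        gid = cohort.truth.contig_sources.get(cid)
        if gid is not None:
            sample = cid.rsplit("_c", 1)[0]
            length = next(c.length for c in cohort.contigs[sample]
                          if c.contig_id == cid)
            weights[gid] = weights.get(gid, 0) + length
    return max(sorted(weights), key=lambda g: weights[g]) if weights else None


def link_pair(cohort: SyntheticCohort, pair_id: str,
              bins_by_sample: dict[str, list[lk.GenomeBin]],
              markers_by_sample: dict[str, list[lk.MarkerGene]],
              identity_threshold: float = 0.975):
    """Link one pair's genome reconstructions across its samples."""
    sample_ids = [s.sample_id for s in cohort.samples if s.pair_id == pair_id]
    bins = [b for sid in sample_ids for b in bins_by_sample.get(sid, [])]
    markers = [m for sid in sample_ids for m in markers_by_sample.get(sid, [])
               if m.source_bin is not None]
    clusters = lk.cluster_marker_proteins(markers, identity_threshold=identity_threshold)
    graph = lk.build_link_graph(bins, clusters)
    communities = lk.detect_communities(graph)
    return bins, graph, communities


def sharing_calls_read_based(cohort: SyntheticCohort,
                             markers_by_sample: dict[str, list[lk.MarkerGene]],
                             clade_identity: float = 0.90,
                             min_presence_jaccard: float = 0.95
                             ) -> tuple[list[st.SharingCall], dict[str, str], list[st.Clade]]:
    """Strain-sharing calls from sample-pooled markers.

    Returns the calls, a clade -> majority-genome map (evaluation only) and
    the clades themselves.
    """
    all_markers = [m for sid in sorted(markers_by_sample) for m in markers_by_sample[sid]]
    clades = st.detect_clades(all_markers, clade_identity=clade_identity,
                              min_presence_jaccard=min_presence_jaccard)
    meta = {s.sample_id: s for s in cohort.samples}
    clade_genome: dict[str, str] = {}
    calls: list[st.SharingCall] = []
    for clade in clades:
        sources = [cohort.truth.contig_sources.get(m.contig_id) for m in clade.members]
        sources = [s for s in sources if s]
        if sources:
            clade_genome[clade.clade_id] = max(sorted(set(sources)), key=sources.count)
        dm = st.clade_distance_matrix(clade, lambda m: m.sample_id)
        if dm is None:
            continue
        tree = st.build_nj_tree(dm)
        coph = st.cophenetic_matrix(tree)
        by_individual: dict[str, list[str]] = {}
        for sid in dm.ids:
            by_individual.setdefault(meta[sid].individual_id, []).append(sid)
        for pair_id in cohort.pairs():
            neo, mom = f"{pair_id}N", f"{pair_id}M"
            if neo not in by_individual or mom not in by_individual:
                continue
            others = {ind: labels for ind, labels in by_individual.items()
                      if ind not in (neo, mom) and meta[labels[0]].role != "control"}
            if not others:
                continue
            calls.append(st.call_strain_sharing(
                coph, by_individual[neo], by_individual[mom], others,
                pair_id=pair_id, clade_id=clade.clade_id, evidence="read_based"))
    return calls, clade_genome, clades


def popgen_analysis(cohort: SyntheticCohort, curated_markers: dict[str, list],
                    seed: int = 0, target_median: float = 20.0,
                    min_support: int = 4, min_af: float = 0.01,
                    estimator: str = "plugin",
                    min_median_depth: float = 20.0, min_breadth: float = 0.40,
                    min_completeness: float = 0.65) -> pd.DataFrame:
    """Per-pair strain population genomics: pi per sample, F_ST per sample pair.

    For each mother-neonate pair and each genome present in both, the
    qualifying samples (median coverage, breadth, marker completeness) are
    downsampled to the target median coverage, SNV-filtered, restricted to
    their common loci, and summarised as pi (per sample) and F_ST
    (mother vs each day and consecutive days).
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 112]))
    rows = []
    days = list(cohort.config.days)
    genome_families: dict[tuple[str, str], set[int]] = {}
    for sid, markers in curated_markers.items():
        for m in markers:
            gid = cohort.truth.contig_sources.get(m.contig_id)
            if gid:
                genome_families.setdefault((gid, sid), set()).add(m.family_id)
    for pair_id in cohort.pairs():
        mom_sample = f"{pair_id}M-F"
        day_samples = [f"{pair_id}N-D{d}" for d in days]
        genomes = sorted({g for (g, sid) in cohort.pileups if sid == mom_sample}
                         & {g for (g, sid) in cohort.pileups
                            if sid in set(day_samples)})
        for gid in genomes:
            qualified = {}
            for sid in [mom_sample] + day_samples:
                pile = cohort.pileups.get((gid, sid))
                if pile is None:
                    continue
                completeness = len(genome_families.get((gid, sid), set())) / lk.N_MARKER_FAMILIES
                summary = pg.CoverageSummary.from_pileup(pile, completeness)
                include, reasons = pg.qualify_genome_sample(
                    summary, min_median_depth, min_breadth, min_completeness)
                if include:
                    down = pg.downsample_to_median(pile, target_median, rng)
                    qualified[sid] = pg.filter_pileup(down, min_support, min_af)
                else:
                    rows.append((gid, pair_id, sid, "", "excluded:" + "+".join(reasons),
                                 float("nan"), 0, estimator))
            if len(qualified) < 2:
                continue
            try:
                loci = pg.intersect_loci(qualified.values())
            except pg.EmptyIntersectionError:
                logger.info("no common loci for %s in pair %s", gid, pair_id)
                continue
            for sid, pile in qualified.items():
                rows.append((gid, pair_id, sid, "", "pi",
                             pg.compute_pi(pile, loci, estimator), loci.size, estimator))
            pairs = [(mom_sample, d) for d in day_samples if d in qualified] + \
                    [(a, b) for a, b in zip(day_samples, day_samples[1:])
                     if a in qualified and b in qualified]
            for a, b in pairs:
                if a not in qualified:
                    continue
                rows.append((gid, pair_id, a, b, "fst",
                             pg.compute_fst(qualified[a], qualified[b], loci, estimator),
                             loci.size, estimator))
    return pd.DataFrame(rows, columns=["genome_id", "pair_id", "sample_1", "sample_2",
                                       "statistic", "value", "n_loci", "mode"])


def functional_analysis(cohort: SyntheticCohort, curated: dict[str, list],
                        alpha: float = 0.05) -> dict[str, Any]:
    """KO profiling, group comparison and enrichment on curated samples."""
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
    diff = fn.differential_kos(table, groups, days, alpha=alpha,
                               individuals=individuals)
    da_kos = {r.ko for r in diff if r.da}
    universe = set(table.counts.columns)
    pathway_map = {pw: kos & universe for pw, kos in cohort.pathway_map.items()}
    enrichment = fn.pathway_enrichment(da_kos, universe, pathway_map)

    rel = table.relative()
    lps_kos = cohort.pathway_map["lps_biosynthesis"]
    cumulative = {sid: fn.cumulative_pathway_abundance(rel.loc[sid].dropna().to_dict(),
                                                       lps_kos)
                  for sid in rel.index}

    # mother vs neonate functional profile similarity per pair
    profile_rows = []
    for pair_id in cohort.pairs():
        mom = f"{pair_id}M-F"
        if mom not in rel.index:
            continue
        pm = rel.loc[mom].fillna(0.0)
        for day in cohort.config.days:
            sid = f"{pair_id}N-D{day}"
            if sid not in rel.index:
                continue
            pn = rel.loc[sid].fillna(0.0)
            if pm.sum() == 0 or pn.sum() == 0:
                continue
            jsd = fn.jensen_shannon((pm / pm.sum()).values, (pn / pn.sum()).values)
            rho = fn.spearman_profile_correlation(pn.values, pm.values)
            profile_rows.append((pair_id, day, jsd, rho))
    profiles = pd.DataFrame(profile_rows, columns=["pair_id", "day", "jsd", "spearman"])
    return {"table": table, "differential": diff, "da_kos": da_kos,
            "universe": universe, "enrichment": enrichment,
            "lps_cumulative": cumulative, "pair_profiles": profiles}


def taxonomic_profiles(cohort: SyntheticCohort,
                       bins_by_sample: dict[str, list[lk.GenomeBin]]
                       ) -> pd.DataFrame:
    """Genus-level relative abundances per sample from binned reconstructions.

    Bin abundance is coverage-weighted contig length; genus labels come from
    the carried genome labels (standing in for external taxonomic
    assignment).  Returns rows (sample_id, genus, abundance).
    """
    rows = []
    for sid, bins in sorted(bins_by_sample.items()):
        weights: dict[str, float] = {}
        for b in bins:
            if b.inferred_label is None:
                continue
            genus = cohort.genomes[b.inferred_label].genus
            mass = sum(next(c.length for c in cohort.contigs[sid]
                            if c.contig_id == cid) *
                       cohort.contig_coverage.get(cid, 0.0)
                       for cid in b.members)
            weights[genus] = weights.get(genus, 0.0) + mass
        total = sum(weights.values())
        for genus, w in sorted(weights.items()):
            rows.append((sid, genus, w / total if total else float("nan")))
    return pd.DataFrame(rows, columns=["sample_id", "genus", "abundance"])


# ------------------------------------------------------------------- run_all

def run_all(config: PipelineConfig) -> dict[str, Any]:
    """Execute the full workflow; returns the run report as a dictionary.

    On stage failure the report marks the stage failed and downstream
    stages are skipped.
    """
    config.validate()
    if config.cohort is None:
        raise PipelineValidationError(
            "file-based inputs must be analysed through the stage functions; "
            "run_all drives the simulated workflow")
    report: dict[str, Any] = {
        "version": __version__,
        "seed": config.cohort.seed,
        "stages": {},
        "parameters": {
            "decontam": config.decontam_params, "binning": config.binning_params,
            "linking": config.linking_params, "strains": config.strains_params,
            "popgen": config.popgen_params, "functional": config.functional_params,
        },
    }
    outdir = Path(config.outdir) if config.outdir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)

    state: dict[str, Any] = {}

    def stage(name, func):
        if name not in config.stages:
            report["stages"][name] = "skipped"
            return True
        try:
            func()
            report["stages"][name] = "ok"
            return True
        except Exception as exc:  # stage failure: record and stop downstream
            logger.exception("stage %s failed", name)
            report["stages"][name] = f"failed: {exc}"
            return False

    def _simulate():
        state["cohort"] = generate_cohort(config.cohort)
        if outdir:
            stio.write_sample_metadata(state["cohort"].samples, outdir / "samples.tsv")
            config.cohort.to_yaml(outdir / "cohort_config.yaml")

    def _decontam():
        cohort = state["cohort"]
        state["curated"], state["removal_report"] = decontaminate_cohort(
            cohort, **config.decontam_params)
        removed = set(state["removal_report"]["contig_id"])
        report["decontamination"] = {
            "n_removed": len(removed),
            "n_kept": sum(len(v) for v in state["curated"].values()),
        }
        state["removed_contigs"] = removed
        if outdir:
            state["removal_report"].to_csv(outdir / "removal_report.tsv",
                                           sep="\t", index=False)

    def _binning():
        cohort = state["cohort"]
        state["bins"], state["markers"] = bin_cohort(
            cohort, state["curated"], **config.binning_params)
        report["binning"] = {
            "n_bins": sum(len(v) for v in state["bins"].values()),
            "mean_completeness": float(np.mean(
                [b.completeness for v in state["bins"].values() for b in v]))
            if any(state["bins"].values()) else float("nan"),
        }

    def _linking():
        cohort = state["cohort"]
        link_calls, link_truth = set(), set()
        n_comm = 0
        ambiguous = []
        for pair_id in cohort.pairs():
            bins, graph, communities = link_pair(
                cohort, pair_id, state["bins"], state["markers"],
                **config.linking_params)
            n_comm += len(communities)
            ambiguous.append(lk.ambiguous_communities(communities, bins))
            for comm in communities:
                ordered = sorted(comm)
                for i, b1 in enumerate(ordered):
                    for b2 in ordered[i + 1:]:
                        link_calls.add((b1, b2))
            label = {b.bin_id: b.inferred_label for b in bins}
            ordered = sorted(label)
            for i, b1 in enumerate(ordered):
                for b2 in ordered[i + 1:]:
                    if label[b1] is not None and label[b1] == label[b2]:
                        link_truth.add((b1, b2))
        state["link_calls"], state["link_truth"] = link_calls, link_truth
        report["linking"] = {"n_communities": n_comm,
                            "n_ambiguous": int(sum(len(a) for a in ambiguous))}

    def _strains():
        cohort = state["cohort"]
        calls, clade_genome, clades = sharing_calls_read_based(
            cohort, state["markers"], **config.strains_params)
        state["sharing_calls"] = calls
        state["clade_genome"] = clade_genome
        shared = [c for c in calls if c.shared]
        report["strains"] = {"n_clades": len(clades), "n_calls": len(calls),
                             "n_shared": len(shared)}
        if outdir:
            pd.DataFrame([{"pair_id": c.pair_id, "clade": c.clade_id,
                           "shared": c.shared, "evidence": c.evidence,
                           "margin": c.margin, "mother_distance": c.mother_distance,
                           "min_other_distance": c.min_other_distance}
                          for c in calls]).to_csv(outdir / "sharing_calls.tsv",
                                                  sep="\t", index=False)

    def _popgen():
        cohort = state["cohort"]
        table = popgen_analysis(cohort, state["markers"],
                                seed=cohort.config.seed, **config.popgen_params)
        state["popgen"] = table
        fst = table[table.statistic == "fst"]
        report["popgen"] = {
            "n_pi": int((table.statistic == "pi").sum()),
            "n_fst": int(len(fst)),
            "median_fst": float(fst["value"].median()) if len(fst) else float("nan"),
        }
        if outdir:
            table.to_csv(outdir / "popgen.tsv", sep="\t", index=False)

    def _functional():
        cohort = state["cohort"]
        out = functional_analysis(cohort, state["curated"],
                                  **config.functional_params)
        state["functional"] = out
        lps = out["enrichment"]
        lps_row = lps[lps.pathway == "lps_biosynthesis"]
        taxa = taxonomic_profiles(cohort, state["bins"])
        state["taxa"] = taxa
        gram_rows = {}
        for sid, sub in taxa.groupby("sample_id"):
            gram_rows[sid] = fn.gram_fraction(dict(zip(sub.genus, sub.abundance)),
                                              cohort.gram_table)
        state["gram"] = gram_rows
        divers = {sid: fn.diversity_indices(dict(zip(sub.genus, sub.abundance)))
                  for sid, sub in taxa.groupby("sample_id")}
        meta = {s.sample_id: s for s in cohort.samples}
        day3 = [s.sample_id for s in cohort.samples if s.day == 3]
        vd = [gram_rows[sid]["negative"] for sid in day3
              if sid in gram_rows and meta[sid].group == "VD"]
        csd = [gram_rows[sid]["negative"] for sid in day3
               if sid in gram_rows and meta[sid].group == "CSD"]
        gram_p = fn.wilcoxon_groups(vd, csd) if vd and csd else float("nan")
        report["functional"] = {
            "n_kos_detected": len(out["universe"]),
            "n_da_kos": len(out["da_kos"]),
            "lps_pathway_q": float(lps_row["q"].iloc[0]) if len(lps_row) else float("nan"),
            "gramneg_day3_vd_mean": float(np.mean(vd)) if vd else float("nan"),
            "gramneg_day3_csd_mean": float(np.mean(csd)) if csd else float("nan"),
            "gramneg_day3_p": float(gram_p),
            "mean_shannon": float(np.nanmean([d[1] for d in divers.values()]))
            if divers else float("nan"),
        }
        if outdir:
            out["enrichment"].to_csv(outdir / "pathway_enrichment.tsv",
                                     sep="\t", index=False)
            taxa.to_csv(outdir / "taxonomic_profiles.tsv", sep="\t", index=False)

    def _evaluate():
        cohort = state["cohort"]
        truth = cohort.truth
        ev = {}
        called_contaminants = state["removed_contigs"]
        ev["decontamination"] = evaluate_calls(
            called_contaminants, truth.contaminant_contigs, "decontamination").to_dict()
        ev["linking"] = evaluate_calls(
            state["link_calls"], state["link_truth"], "linking").to_dict()
        shared = {(c.pair_id, state["clade_genome"].get(c.clade_id))
                  for c in state["sharing_calls"] if c.shared}
        shared = {t for t in shared if t[1] is not None}
        ev["sharing"] = evaluate_calls(shared, truth.transmitted, "sharing").to_dict()
        report["evaluation"] = ev

    for name, func in (("simulate", _simulate), ("decontam", _decontam),
                       ("binning", _binning), ("linking", _linking),
                       ("strains", _strains), ("popgen", _popgen),
                       ("functional", _functional), ("evaluate", _evaluate)):
        if not stage(name, func):
            break

    if outdir:
        (outdir / "report.json").write_text(
            json.dumps(report, indent=1, sort_keys=True, default=str))
    return report
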