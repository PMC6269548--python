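"""Functional (KO) profiling, group comparisons and enrichment statistics.

Genes are assigned to KEGG Orthology (KO) groups by a best-bit-score rule,
aggregated into a sample x KO count table, and compared across delivery
groups with rank-based tests plus Benjamini-Hochberg FDR control.  KO sets
flagged as differentially abundant feed a hypergeometric pathway-enrichment
test and a Fisher exact test for enrichment of individual genomes in
differential functions.  Profile-level comparisons use Jensen-Shannon
divergence and Spearman correlation, and community structure is summarised
with richness, Shannon diversity, Pielou evenness and Gram-stain fractions.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import jensenshannon
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


@dataclass
class GeneHit:
    """Candidate KO assignments for one predicted gene."""

    gene_id: str
    sample_id: str
    candidates: dict[str, float]  # KO id -> bit score
    read_count: int

    def __post_init__(self) -> None:
        if self.read_count < 0:
            raise ValueError("read count must be >= 0")
        for ko, score in self.candidates.items():
            if not math.isfinite(score):
                raise ValueError(f"non-finite bit score for {ko}")


@dataclass
class KOTable:
    """Sample x KO read-count matrix with a relative-abundance view."""

    counts: pd.DataFrame  # rows = samples, columns = KOs

    def relative(self) -> pd.DataFrame:
        """Row-normalised abundances; all-zero samples are flagged and left NaN."""
        totals = self.counts.sum(axis=1)
        empty = totals[totals == 0].index.tolist()
        if empty:
            logger.warning("samples with no assigned KOs: %s", empty)
        return self.counts.div(totals.replace(0, np.nan), axis=0)


@dataclass
class DifferentialResult:
    ko: str
    p_values: dict[str, float]
    q_values: dict[str, float]
    directions: dict[str, int]
    da: bool


def assign_best_ko(hit: GeneHit, n_target_genes: int) -> str | None:
    """Best-hit KO assignment.

    The KO with the highest bit score is assigned iff that score is strictly
    greater than log2(n_target_genes); score ties go to the
    lexicographically smallest KO id.  Returns None when no candidate
    qualifies.
    """
    if n_target_genes < 1:
        raise ValueError("n_target_genes must be >= 1")
    if not hit.candidates:
        return None
    best_ko = min(hit.candidates, key=lambda k: (-hit.candidates[k], k))
    if hit.candidates[best_ko] > math.log2(n_target_genes):
        return best_ko
    return None


def aggregate_ko_counts(assignments: Mapping[str, str | None],
                        hits: Iterable[GeneHit]) -> KOTable:
    """Sum gene read counts per (sample, KO); unassigned genes are dropped."""
    acc: dict[str, dict[str, int]] = {}
    for h in hits:
        acc.setdefault(h.sample_id, {})
        ko = assignments.get(h.gene_id)
        if ko is None:
            continue
        acc[h.sample_id][ko] = acc[h.sample_id].get(ko, 0) + h.read_count
    table = pd.DataFrame.from_dict(acc, orient="index")
    table = table.reindex(index=sorted(acc), columns=sorted(table.columns))
    return KOTable(table.fillna(0).astype(int))


def jensen_shannon(p, q, base: float = 2.0, distance: bool = False) -> float:
    """Jensen-Shannon divergence (default) or distance between two profiles.

    Inputs may be mappings or aligned arrays; mappings are joined over the
    union support with absent keys at 0.  With base-2 logarithms the
    divergence lies in [0, 1] and equals 1 for disjoint supports.
    """
    if isinstance(p, Mapping) or isinstance(q, Mapping):
        keys = sorted(set(p) | set(q))
        p = np.array([p.get(k, 0.0) for k in keys], dtype=float)
        q = np.array([q.get(k, 0.0) for k in keys], dtype=float)
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if (p < 0).any() or (q < 0).any():
        raise ValueError("profiles must be non-negative")
    for name, v in (("p", p), ("q", q)):
        s = v.sum()
        if s <= 0 or abs(s - 1.0) > 1e-6:
            raise ValueError(f"profile {name} is not normalised (sum={s:.6g})")
    dist = float(jensenshannon(p, q, base=base))
    return dist if distance else dist * dist


def spearman_profile_correlation(profile_a, profile_b) -> float:
    """Spearman rank correlation of two profiles over their union support.

    Average ranks resolve ties; a zero-variance profile makes the
    coefficient undefined (NaN, flagged).
    """
    if isinstance(profile_a, Mapping) or isinstance(profile_b, Mapping):
        keys = sorted(set(profile_a) | set(profile_b))
        profile_a = np.array([profile_a.get(k, 0.0) for k in keys], dtype=float)
        profile_b = np.array([profile_b.get(k, 0.0) for k in keys], dtype=float)
    a = np.asarray(profile_a, dtype=float)
    b = np.asarray(profile_b, dtype=float)
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        logger.warning("zero-variance profile: Spearman correlation undefined")
        return float("nan")
    rho, _ = stats.spearmanr(a, b)
    return float(rho)


def wilcoxon_groups(values_a: Sequence[float], values_b: Sequence[float],
                    paired: bool = False) -> float:
    """Two-sided rank test p-value between two groups of observations.

    Unpaired data use the Wilcoxon rank-sum (Mann-Whitney) test: exact
    enumeration when the combined sample size is at most 20 and there are no
    ties, the tie-corrected normal approximation otherwise.  Paired data use
    the signed-rank test.  Completely tied data give p = 1 with a warning.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("each group needs at least one observation")
    if paired:
        if a.size != b.size:
            raise ValueError("paired mode needs equally sized groups")
        diffs = a - b
        if np.all(diffs == 0):
            warnings.warn("all paired differences are zero; p = 1")
            return 1.0
        return float(stats.wilcoxon(a, b, zero_method="wilcox",
                                    alternative="two-sided").pvalue)
    pooled = np.concatenate([a, b])
    if np.unique(pooled).size == 1:
        warnings.warn("all observations tied; p = 1")
        return 1.0
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (pooled.size <= 20 and not has_ties) else "asymptotic"
    return float(stats.mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue)


def adjust_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def differential_kos(table: KOTable, groups: Mapping[str, str],
                     days: Mapping[str, int | None],
                     include_days: Sequence[int] = (3, 5),
                     comparisons: Sequence[tuple[str, str]] = (("VD", "CSD"),
                                                               ("VD", "CSD_SGA")),
                     alpha: float = 0.05,
                     individuals: Mapping[str, str] | None = None
                     ) -> list[DifferentialResult]:
    """Rank-based differential-abundance screen of KOs between delivery groups.

    For each KO and each comparison, relative abundances from the included
    days are compared with a two-sided rank-sum test; directions are signs
    of median differences (first group minus second); p-values are
    BH-adjusted across KOs within each comparison.  A KO is flagged
    differentially abundant iff its adjusted p-value is < alpha in at least
    one comparison and the direction of change agrees across the
    comparisons that could be run.

    When ``individuals`` maps sample ids to individual ids, each
    individual's eligible samples are pooled (averaged) into one
    observation before testing, so repeated sampling of the same neonate
    does not masquerade as independent evidence.
    """
    rel = table.relative()
    eligible = [s for s in rel.index if days.get(s) in set(include_days)]
    rel = rel.loc[eligible].fillna(0.0)
    if individuals is not None:
        ind_group = {}
        for s in eligible:
            ind = individuals.get(s, s)
            if ind in ind_group and ind_group[ind] != groups[s]:
                raise ValueError(f"individual {ind} appears in two groups")
            ind_group[ind] = groups[s]
        rel = rel.groupby([individuals.get(s, s) for s in rel.index]).mean()
        groups = ind_group
        eligible = list(rel.index)
    by_group: dict[str, list[str]] = {}
    for s in eligible:
        by_group.setdefault(groups[s], []).append(s)
    results: list[DifferentialResult] = []
    p_cols: dict[str, list[float]] = {}
    dir_cols: dict[str, list[int]] = {}
    comp_names = []
    for g1, g2 in comparisons:
        name = f"{g1}_vs_{g2}"
        if not by_group.get(g1) or not by_group.get(g2):
            logger.warning("comparison %s skipped: group missing", name)
            continue
        comp_names.append(name)
        pvals, dirs = [], []
        x_all = rel.loc[by_group[g1]]
        y_all = rel.loc[by_group[g2]]
        for ko in rel.columns:
            x = x_all[ko].values
            y = y_all[ko].values
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                pvals.append(wilcoxon_groups(x, y))
            dirs.append(int(np.sign(np.median(x) - np.median(y))))
        p_cols[name] = pvals
        dir_cols[name] = dirs
    q_cols = {name: adjust_fdr(p_cols[name]) for name in comp_names}
    for i, ko in enumerate(rel.columns):
        qs = {name: float(q_cols[name][i]) for name in comp_names}
        ds = {name: dir_cols[name][i] for name in comp_names}
        significant = any(q < alpha for q in qs.values())
        dirs = list(ds.values())
        same_dir = len(dirs) > 0 and all(d == dirs[0] and d != 0 for d in dirs)
        results.append(DifferentialResult(
            ko=ko,
            p_values={name: float(p_cols[name][i]) for name in comp_names},
            q_values=qs, directions=ds, da=bool(significant and same_dir)))
    return results


def pathway_enrichment(da_kos: set[str], universe: set[str],
                       pathway_map: Mapping[str, set[str]]) -> pd.DataFrame:
    """Hypergeometric enrichment of pathways among differentially abundant KOs.

    For each pathway, the one-sided upper-tail probability of drawing at
    least the observed overlap when |da_kos| KOs are sampled from the
    universe; BH adjustment across pathways.  Pathways with no KO in the
    universe get p = 1 and are flagged.
    """
    if not da_kos <= universe:
        raise ValueError("da_kos must be a subset of the universe")
    M, n_draws = len(universe), len(da_kos)
    rows = []
    for pw, kos in sorted(pathway_map.items()):
        in_universe = kos & universe
        overlap = len(in_universe & da_kos)
        if not in_universe:
            logger.warning("pathway %s has no KO in the universe", pw)
            p = 1.0
        else:
            p = float(stats.hypergeom.sf(overlap - 1, M, len(in_universe), n_draws))
        rows.append((pw, len(in_universe), overlap, p, len(in_universe) == 0))
    df = pd.DataFrame(rows, columns=["pathway", "pathway_size", "overlap", "p", "empty"])
    df["q"] = adjust_fdr(df["p"].values)
    return df


@dataclass
class EnrichmentResult:
    odds_ratio: float
    p_value: float
    table: tuple[int, int, int, int]
    haldane: bool = False
    degenerate: bool = False


def genome_function_enrichment(bin_kos: set[str], da_set: set[str],
                               universe: set[str]) -> EnrichmentResult:
    """Fisher exact test: is a genome's KO repertoire enriched in a KO set?

    The 2x2 table partitions the universe by membership in the genome and in
    ``da_set``.  The sample odds ratio ad/bc is reported (Haldane 0.5
    correction on zero cells, flagged); the p-value is the exact two-sided
    Fisher probability.  Degenerate margins give p = 1 and an undefined OR.
    """
    if not (bin_kos <= universe and da_set <= universe):
        raise ValueError("input sets must be subsets of the universe")
    a = len(bin_kos & da_set)
    b = len(bin_kos - da_set)
    c = len(da_set - bin_kos)
    d = len(universe - bin_kos - da_set)
    if min(a + b, c + d, a + c, b + d) == 0:
        logger.warning("degenerate margin in 2x2 table %s", (a, b, c, d))
        return EnrichmentResult(float("nan"), 1.0, (a, b, c, d), degenerate=True)
    haldane = 0 in (a, b, c, d)
    if haldane:
        orr = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    else:
        orr = (a * d) / (b * c)
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return EnrichmentResult(float(orr), float(p), (a, b, c, d), haldane=haldane)


def cumulative_pathway_abundance(profile: Mapping[str, float],
                                 pathway_kos: set[str]) -> float:
    """Sum of relative abundances of the pathway's KOs present in a sample."""
    return float(sum(v for k, v in profile.items() if k in pathway_kos))


def gram_fraction(abundances: Mapping[str, float],
                  gram_table: Mapping[str, str]) -> dict[str, float]:
    """Aggregate genus-level relative abundances by Gram-stain label.

    Unlabelled genera count as unknown (logged) and are never folded into
    the negative/positive fractions.
    """
    out = {"negative": 0.0, "positive": 0.0, "unknown": 0.0}
    for genus, ab in abundances.items():
        label = gram_table.get(genus)
        if label not in ("negative", "positive"):
            if label is None:
                logger.info("genus %s missing from Gram table; counted unknown", genus)
            label = "unknown"
        out[label] += float(ab)
    return out


def diversity_indices(profile: Mapping[str, float] | Sequence[float]
                      ) -> tuple[float, float, float]:
    """(richness, Shannon H with natural logs, Pielou J = H/ln(richness)).

    Pielou evenness is undefined (NaN) for a single-taxon community; an
    all-zero profile yields NaN for every index.
    """
    values = np.asarray(list(profile.values()) if isinstance(profile, Mapping)
                        else profile, dtype=float)
    if (values < 0).any():
        raise ValueError("abundances must be non-negative")
    total = values.sum()
    if total == 0:
        return float("nan"), float("nan"), float("nan")
    p = values[values > 0] / total
    richness = int(p.size)
    shannon = float(-(p * np.log(p)).sum())
    pielou = shannon / math.log(richness) if richness > 1 else float("nan")
    return float(richness), shannon, pielou
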