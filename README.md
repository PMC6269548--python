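# straintrace

Strain-level analysis of mother-to-neonate gut microbiome transmission by
delivery mode, for microbiome researchers working with paired
mother-infant metagenomes — and for anyone who wants to validate such a
workflow end to end without access to patient data.

Newborn stool in the first days of life yields very little microbial DNA,
so its metagenomes are contaminated by artefactual sequences from
extraction kits and library preparation, and the question of which strains
a neonate actually inherited from its mother demands nucleotide-level
resolution. `straintrace` implements the complete computational chain:

1. **Artefact removal** against a sequenced negative control: a canonical
   k-mer containment screen, then joint tetranucleotide binning of sample
   and control contigs (CLR-transformed frequencies, 2-D projection,
   DBSCAN); every bin with total length < 10 Mbp holding > 0.01% of the
   control's total contig length is removed as a reconstructed artefact
   genome.
2. **Genome reconstruction and linking**: per-sample binning on
   composition plus coverage; bins linked across a mother-neonate pair by
   clustering their 35 universal single-copy marker proteins at 97.5%
   identity and detecting communities (greedy modularity) in the weighted
   co-occurrence graph. Completeness = marker families present / 35.
3. **Strain tracking**: neighbour-joining trees over marker p-distances
   per clade; a neonate *shares* the maternal strain iff its cophenetic
   distance to the mother's markers is strictly smaller than to any other
   individual's.
4. **Population genomics** from allele-count pileups: genome-sample
   alignments qualify at median coverage >= 20X, breadth >= 40% and
   completeness > 65%; qualified pileups are binomially downsampled to a
   20X median, SNVs require >= 4 supporting reads and allele frequency
   >= 1%, and all statistics are restricted to loci covered in every
   compared sample. Then per sample

   &pi; = mean over loci of (1 &minus; &Sigma;<sub>a</sub> f<sub>a</sub>&sup2;),  0 &le; &pi; < 1,

   and per sample pair

   F<sub>ST</sub> = 1 &minus; mean(&pi;&#8321;, &pi;&#8322;) / &pi;<sub>between</sub>,  &pi;<sub>between</sub> = mean over loci of (1 &minus; &Sigma;<sub>a</sub> f&#8321;<sub>a</sub> f&#8322;<sub>a</sub>),

   with a without-replacement ("unbiased") estimator variant selectable.
5. **Functional analysis**: best-bit-score KO assignment (accepted only
   above log2 of the number of target genes), sample x KO tables,
   rank-sum + Benjamini-Hochberg differential abundance between delivery
   groups with a same-direction rule across comparisons, hypergeometric
   pathway enrichment, Fisher-exact genome-level enrichment,
   Jensen-Shannon divergence, Spearman profile correlation, Gram-stain
   fractions and Shannon/Pielou/richness indices.

Because the real cohort cannot be redistributed, the package ships a
first-class **synthetic cohort generator** (`straintrace.simulate`): seeded
paired mother-neonate cohorts over three delivery groups (vaginal
delivery VD, caesarean CSD, caesarean small-for-gestational-age CSD_SGA)
with within-host allele-frequency spectra, a transmission bottleneck,
contaminant genomes planted in low-biomass samples and the control, and a
Gram-negative-restricted LPS-biosynthesis-like pathway enriched in VD
neonates — all with machine-readable ground truth, so every stage is
scored by parameter recovery.

## A worked example

```python
from straintrace.pipeline import decontaminate_cohort, sharing_calls_read_based
from straintrace.simulate import CohortConfig, generate_cohort
from straintrace.validation import curated_markers

cohort = generate_cohort(CohortConfig(
    n_pairs_per_group={"VD": 2, "CSD": 2, "CSD_SGA": 1},
    genome_length=50_000, seed=11))
curated, _ = decontaminate_cohort(cohort)
calls, clade_genome, clades = sharing_calls_read_based(
    cohort, curated_markers(cohort, curated))
for call in calls[:3]:
    print(call.pair_id, clade_genome[call.clade_id], call.shared,
          f"margin={call.margin:+.4f}")
```

prints (seed 11):

```
P03 G07 True margin=+0.0183
P04 G07 True margin=+0.0195
P05 G07 True margin=+0.0186
```

Each line is one mother-neonate pair and one genome-level clade: `True`
means the neonate's marker sequences sit strictly closer to its own
mother's than to any other individual's, and the margin (in p-distance
units) is the gap to the nearest competitor — here ~2% amino-acid
divergence, i.e. unambiguous maternal origin. On this cohort the calls
recover 11 of 11 planted transmissions with one false call. The
`examples/` directory walks through every other capability the same way
(decontamination, genome linking, &pi;/F<sub>ST</sub>, functional
enrichment, full pipeline), and

```bash
straintrace run-all --seed 11 --out runs/demo
```

executes everything and writes a JSON report with per-stage
precision/recall against the ground truth.

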