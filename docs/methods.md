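# Methods

This note documents the models and procedures implemented in
`straintrace`, the assumptions behind them, the defaults that matter and
why, what the synthetic cohorts do and do not emulate, and the numerical
choices a maintainer would want written down.

## The analysis problem

Paired mother-neonate metagenomes sampled around delivery are used to ask
three questions: (1) which sequences in the low-biomass neonatal samples
are artefacts of DNA extraction and library preparation rather than
genuine gut microbes; (2) which microbial strains in a neonate descend
from its own mother's populations (vertical transmission) as opposed to
unrelated environmental strains; and (3) how the delivery mode (vaginal,
caesarean, caesarean + small-for-gestational-age) reshapes the
taxonomic and functional profile of the early gut, in particular the
representation of Gram-negative bacteria and their lipopolysaccharide
(LPS) biosynthesis genes.

## Artefact removal

Two complementary stages run against a sequenced negative-control sample
prepared with the same reagents as the study samples.

*k-mer screen.* A study contig is removed when >= 90% of its canonical
31-mers occur in the control's contig set. This replaces read-vs-contig
mapping with contig-level containment: the artifact works from assembled
contigs, and containment of canonical k-mers is the standard alignment-free
equivalent. k = 31 and the 0.9 containment threshold are exposed.
Contigs shorter than k cannot be assessed and are kept with a warning.

*Joint binning.* Surviving sample contigs are embedded together with the
control contigs using canonical tetranucleotide frequencies
(reverse-complement-collapsed, 136 dimensions), centred-log-ratio
transformed with pseudocount 1, and projected to 2-D. The default
projection is PCA with a fixed sign convention (each component is flipped
so its largest-magnitude loading is positive), which makes the embedding
exactly reproducible; a seeded t-SNE is selectable for visual fidelity to
stochastic-neighbour embeddings. DBSCAN clusters the embedding with
min_points = 5 and, unless given, eps set to the 95th percentile of
4-nearest-neighbour distances — a declared heuristic, logged on every
run, because no canonical value exists for these scales. Every bin whose
total length is strictly below 10 Mbp and whose member contigs from the
control sample amount to strictly more than 0.01% of the control's total
contig length is flagged as a reconstructed artefact genome, and its
sample contigs are removed. Both inequalities are deliberately strict;
the 0.01% denominator is the control sample's total contig length. An
rRNA-exclusion hook exists for real data (rRNA confounds composition
binning); synthetic contigs carry none, so it defaults to empty.

A contig caught by both stages is reported once, attributed to the
screen. Removal is monotone in the control set: adding control contigs
can only grow the removed set.

## Genome reconstruction and cross-sample linking

Within one sample, curated contigs are clustered in a feature space of
the 2-D composition embedding joined with log10 coverage (each axis
standardised), again with DBSCAN; bins below 100 kb total length are
discarded as fragments. Completeness of a bin is the fraction of 35
universal single-copy marker-protein families with at least one hit among
its contigs. The 35 families are modelled as opaque identifiers; real
marker HMMs are not shipped, and taxonomy is attached externally (the
synthetic route carries the generator's genome label for evaluation
only).

To link reconstructions across the samples of one mother-neonate pair,
all the pair's marker proteins are clustered greedily at 97.5% global
identity: sequences are processed by decreasing length (ties by
identifier), each joining the first cluster whose representative it
matches at or above the threshold, else founding a new cluster. Identity
is matches / alignment length under global alignment with unit match
score; gap columns count against identity. This reproduces the greedy
incremental scheme of word-based clustering tools with exact identities
in place of their word heuristics. A membership decision uses a banded
edit-distance bound first and computes the full alignment only when the
bound cannot decide, which changes nothing about the result. Bins become
nodes of a graph whose edge weights count the marker clusters in which
both bins are represented; communities under greedy modularity
maximisation are the cross-sample genomes. Communities containing more
than one bin from a single sample are emitted in an "ambiguous" report —
the automated stand-in for manual inspection.

## Strain tracking and the sharing criterion

Strain-level evidence comes from marker phylogenies per clade. Because
no reference marker database is in scope, clades are detected from the
data: markers are clustered per family at a coarse 90% identity (wide
enough to span within-species strain divergence, far above between-genome
identity), and per-family clusters whose sample-presence sets agree at
Jaccard >= 0.95 are merged into clades by connected components — the 35
single-copy families of one genome necessarily travel together across
samples, so same-genome clusters have identical presence sets, while the
closest co-circulating genomes observed in simulation reach Jaccard
about 0.89. Within a clade, each entity (a sample for read-based
evidence, a bin for genome-based evidence) keeps one sequence per family
(smallest identifier, deterministic), and pairwise distances are mean
p-distances over the families both entities share (gap columns excluded;
entities sharing no family default to distance 1).

The distance matrix feeds neighbour joining (scikit-bio); negative branch
lengths are clamped to zero. On additive matrices NJ is exact, which the
tests verify. A neonate is called to share a strain with its mother iff
the cophenetic distance between its leaves and the mother's leaves is
*strictly* smaller than the distance to the leaves of every other
individual; an individual with several samples or bins is represented by
its minimum. Exact ties are conservatively not shared. The margin
(nearest-other distance minus mother distance) is exported so users can
impose their own evidence threshold; no canonical quantitative cut-off
exists for "strength of evidence", so none is imposed.

## Population genomics from pileup columns

Reads are never represented: the atomic unit is the per-position allele
count vector, which is sufficient statistics for every formula below.

A genome-sample combination qualifies when median coverage >= 20X,
breadth (fraction of positions with depth >= 1) >= 40%, and genome
completeness > 65% (strict). Qualified pileups are thinned to a median
of 20X by one binomial draw per allele per column with probability
target/median — a thinning model rather than exact read subsampling,
because reads do not exist here. SNVs require a non-major allele with
>= 4 supporting reads and allele frequency >= 1% (both inclusive);
columns where no minor allele passes are treated as monomorphic, i.e.
sub-threshold minor counts are dropped. All per-sample and per-pair
statistics are computed over the loci covered in *every* sample compared
(an empty intersection aborts that comparison with a log entry).

Per locus with allele frequencies f_a = count_a / depth:

- plugin (with replacement): pi_l = 1 - sum_a f_a^2
- unbiased (without replacement): pi_l = (d^2 - sum_a c_a^2) / (d (d-1)),
  loci with depth < 2 excluded with a warning

and pi is the mean of pi_l over the whole locus set — monomorphic covered
loci contribute 0 (a per-site definition; a variant-loci-only option
exists but is off by default). Between two samples, the per-locus
between-population diversity is 1 - sum_a f1_a f2_a, and

    F_ST = 1 - mean(pi_1, pi_2) / pi_between,

all three averaged over the same loci. The plugin estimator is the
default because it makes F_ST of a sample against itself exactly 0; the
unbiased mode is provided because the verbal definition of pi ("two reads
chosen at random") admits the without-replacement reading. The estimator
mode is recorded in every output row. F_ST is reported missing when
pi_between is 0 over all loci. A minimum-alignment-identity option for
read mapping is a pass-through here: synthetic pileups are generated per
genome, so cross-species read bleed cannot arise.

## Functional analysis

A gene's KO is the candidate with the highest bit score, accepted only if
that score strictly exceeds log2(number of target genes); score ties go
to the lexicographically smallest KO. Read counts aggregate per
(sample, KO); the relative view row-normalises, flagging samples with no
assignments. Differential abundance between delivery groups replaces a
negative-binomial Wald model with a deliberately simple rank-based test:
per KO and per comparison (VD vs CSD, VD vs CSD_SGA), the day-3 and
day-5 relative abundances are pooled *within* each neonate (averaged into
one observation per individual — repeated sampling of the same infant is
not independent evidence; a genome absent from a neonate is absent on
both days, so treating its two samples as separate units ran a measured
type-I rate near 0.11) and compared with a two-sided rank-sum across
neonates (exact enumeration when the pooled n <= 20 and untied,
tie-corrected normal approximation otherwise), BH adjustment across KOs
within each comparison, direction = sign of the median difference. This
individual-level pooling is the rank-based analogue of the replaced count
model's day-as-covariate adjustment; with it the measured type-I rate on
null cohorts sits at ~0.04 (reported fresh by the acceptance script, not
assumed). A KO is flagged differentially abundant iff adjusted p < 0.05
in at least one comparison *and* the direction agrees across the
comparisons that ran — the same-direction conjunction is kept exactly.
Sample-level testing remains available by omitting the
individual-mapping argument.

Pathway enrichment of the flagged KO set uses the one-sided
hypergeometric upper tail including the observed overlap, with the
universe equal to all KOs detected in the cohort, BH across pathways.
Genome-level enrichment uses the 2x2 sample odds ratio ad/bc (Haldane 0.5
on zero cells, flagged) with the exact two-sided Fisher probability.
Profile comparisons use Jensen-Shannon divergence with base-2 logarithms
(range [0, 1]; a square-root distance variant is selectable) and Spearman
correlation with average ranks over the union KO support. Community
summaries use natural-log Shannon diversity, Pielou evenness
(undefined at richness 1) and richness; Gram-stain fractions aggregate
genus abundances by a user-supplied genus -> Gram table, with unlabelled
genera reported as "unknown" and never folded into the labelled
fractions.

## The synthetic cohort generator

The generator emulates the statistical structure the analysis assumes,
at a scale that runs in seconds per cohort.

**Design.** Defaults: 8 VD / 7 CSD / 5 CSD_SGA pairs (roughly half the
15/12/6 study design, preserving the imbalance — and large enough that
an exact across-neonate rank test retains a usable p-value floor after
FDR control over an 800-KO universe), neonatal faecal
samples on days 1/3/5, one pre-delivery maternal faecal sample per
mother, one cell-culture control; 9 genomes of 200 kb (3 Gram-negative
enteric, 2 Gram-positive enteric, 2 skin-associated firmicutes, 2
contaminants). Real genomes are Mbp-scale; 200 kb keeps pileup arrays
small while leaving ~40 contigs per genome for binning. Genome sequences
are i.i.d. dinucleotide-block chains with class GC targets (0.50 / 0.40 /
0.33 / 0.65) perturbed per genome, giving each genome a distinct
tetranucleotide signature, as real genomes have. Contaminants are
high-GC on purpose — mirroring the high-GC reagent-contaminant genera —
so composition binning can isolate them.

**Carriage, transmission, colonisation.** Mothers carry each genome with
class probabilities (0.95 / 0.90 / 0.60). A carried strain transmits to
the neonate with (group, class) probabilities defaulting to VD
0.80/0.60/0.20 and CSD(+SGA) 0.15/0.30/0.70 (Gram-negative /
Gram-positive enteric / skin) — the qualitative pattern of frequent
maternal enteric transmission under vaginal delivery and skin-flora
seeding under caesarean delivery. Non-transmitted genomes can still be
acquired environmentally as unrelated strains (class-specific: skin 0.7,
Gram-positive enteric 0.1, Gram-negative 0.05), and every neonate
receives at least one skin coloniser — the neonatal gut is never sterile.
Relative abundances are Dirichlet draws with class-weighted
concentrations (maternal gut enteric-dominated: 4/3/1; neonatal gut
skin-dominated: 2/2/8); in VD neonates the concentration of every
Gram-negative genome present is multiplied by the LPS effect size
(default 4), which is what plants the Gram-negative/LPS contrast.
Day-to-day compositional drift redraws each day's shares around the
neonate's base composition (Dirichlet concentration 12): first-week
infant microbiomes genuinely churn, and without that churn day-3 and
day-5 samples would be statistical duplicates.

**Strains and allele frequencies.** Each individual's strain of a genome
is the reference mutated at 1% per site (unrelated strains are therefore
~2% apart); a transmitted strain copies the mother's consensus with a
2e-5 residual substitution rate and its markers with 2e-4 per residue.
Within-host polymorphism sits at 0.5% of sites with minor-allele
frequencies Beta(0.8, 8) (mostly rare minor alleles; implied true pi
~7e-4, a realistic strain-level diversity). At transmission, each site's
frequency f is redrawn from Beta(f/s, (1-f)/s) with s = 0.3 (the
bottleneck scale — the study quantifies no bottleneck, so this free
parameter was set once to produce a clear mother-vs-neonate
differentiation signal while day-to-day drift uses the same kernel at
s = 0.02). Pileup depth per position is Poisson(mean site depth x
relative abundance) with site depths 120X (faecal), 80X (vaginal), 60X
(control); allele counts are binomial around the true frequencies.
Contaminant genomes are sequence-identical in every sample, as reagent
DNA is.

**Markers, KOs, genes.** Each genome carries 35 marker proteins of
60-100 residues placed at fixed genome positions, so each marker rides on
exactly one contig and binning quality propagates into completeness. The
KO universe (800) splits into a 45% core present in every genome,
class-specific pools (10% Gram-negative — the first 12 of which form the
LPS-biosynthesis-like pathway carried by all Gram-negative enteric
genomes and only them — 7.5% Gram-positive, 5% skin, 5% contaminant) and
a shared accessory pool; gene read counts are Poisson around abundance x
600. A large core keeps class-responsive KOs a minority of the universe,
as in real KO catalogues. Gene-to-KO hit tables carry decoy candidates
at lower bit scores and ~5% weak hits below the acceptance threshold.

**What is not simulated** — and therefore what passing tests cannot
attest to on real data: sequencing error in pileups (the >= 4-read SNV
support filter is exercised structurally, not against error noise),
indels and rearrangements, intra-sample strain mixtures of the same
genome, rRNA on contigs, 16S amplicon data, host reads, twin pairs,
feeding and antibiotics covariates, and the wet-lab immunology
downstream of the LPS finding.

## Orchestration and evaluation

`run_all` executes simulate -> decontaminate -> bin -> link -> strain
tracking -> population genomics -> functional analysis -> evaluation,
persists stage outputs as TSV/JSON in the chosen formats, and is
deterministic for a fixed configuration and seed; a failed stage marks
the report and skips downstream stages. In the simulated workflow, read
mapping against reconstructed genomes is replaced by pileups keyed to the
generating genome, and the marker-to-genome attribution used for
completeness gating and evaluation comes from the generator's record; on
real data both would come from the mapping itself. Evaluation is
set-based precision/recall/F1 on three tasks: removed contig ids against
planted contaminants, co-communitied bin pairs against same-genome bin
pairs, and shared (pair, genome) calls against planted transmissions
(precision and recall defined as 1.0 when both the call set and its
complement term are empty).

Benchmarks (in `straintrace.validation`, consumed by the test suite and
`scripts/acceptance.py`) run 20 default cohorts per pass. The numbers
they produce — contaminant recall, bona fide loss, sharing
precision/recall, F_ST ordering fraction and medians, LPS-pathway
enrichment power, Gram-negative contrast direction, null type-I rate —
are computed fresh on every run; none is stored.

## Known limitations

- The day-pooled rank-sum differential test ignores within-neonate
  correlation; its measured type-I rate (~0.05-0.07) is reported, not
  corrected. A mixed-effects or count-model engine would be the upgrade
  path.
- Clade detection by presence-set agreement assumes single-copy markers
  and complete marker recovery per sample; heavy marker dropout would
  fragment clades (the genome-based route through bins is more tolerant,
  at the cost of binning errors).
- DBSCAN's eps heuristic is scale-dependent; on real embeddings it should
  be inspected, which is why every run logs it.
- Composition-based artefact flagging can remove a bona fide genome whose
  oligonucleotide signature happens to sit next to a contaminant's: in
  simulation, a Gram-negative genome whose realised GC drifted to 0.57
  co-clustered with a 0.60-GC contaminant cohort-wide. The aggregate
  bona fide loss stays around 1%, but per-cohort losses above 10% occur,
  which is exactly why a control based on sequences homologous to real
  community members would be dangerous.
- The NJ implementation clamps negative branch lengths to zero without
  redistributing the deficit to the sister branch; on the p-distance
  scales here the difference is negligible and additive cases are exact.
- Two genomes co-occurring in *every* sample (as the two contaminants do)
  are merged by clade detection; their within-clade distances are zero in
  the contaminant case, so sharing calls degrade to conservative ties,
  but the situation is worth knowing about.
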