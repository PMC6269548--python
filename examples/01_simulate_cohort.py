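"""Generate a small synthetic mother-neonate cohort and look at its ground truth.

The generator plants everything the downstream analysis is supposed to
recover: which strains each neonate inherited from its mother, which
contigs are extraction/library artefacts, and which gene functions differ
between delivery groups.
"""

from straintrace.simulate import CohortConfig, generate_cohort

config = CohortConfig(
    n_pairs_per_group={"VD": 2, "CSD": 2, "CSD_SGA": 1},
    genome_length=50_000,
    seed=11,
)
cohort = generate_cohort(config)

print(f"samples: {len(cohort.samples)} "
      f"({sum(s.role == 'neonate' for s in cohort.samples)} neonatal, "
      f"{sum(s.role == 'mother' for s in cohort.samples)} maternal, 1 control)")
print(f"genomes: {len(cohort.genomes)}")
for gid, rec in cohort.genomes.items():
    print(f"  {gid}: {rec.genus:15s} {rec.genome_class:16s} Gram-{rec.gram}")
print(f"planted transmissions (pair, genome): {sorted(cohort.truth.transmitted)}")
print(f"contaminant contigs planted in study samples: "
      f"{len(cohort.truth.contaminant_contigs)}")
print(f"KOs with a planted delivery-group effect: "
      f"{len(cohort.truth.planted_da_kos)}")
# Each (pair, genome) in `transmitted` means the neonate's strain population
# descends from the mother's through the birth bottleneck; everything else a
# neonate carries is an unrelated environmental strain.
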