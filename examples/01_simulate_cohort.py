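"""Simulate a small multi-breed SNP-array cohort with implanted CNVs.

The generator draws per-breed allele frequencies from the Balding-Nichols
model (a known F_ST truth), Hardy-Weinberg genotypes, a Poisson number of
deletion/duplication events per animal, and X/Y intensities consistent with
both. Everything is reproducible from the seed.
"""

import ovinecnv as oc

config = oc.SimConfig(
    n_breeds=2,
    n_per_breed=10,
    n_chromosomes=2,
    snps_per_chromosome=1000,
    chrom_length_bp=50_000_000,
    fst_target=0.10,
    cnvs_per_individual_mean=2.0,
    seed=42,
)
cohort = oc.simulate_cohort(config)

print(f"cohort: {cohort.n_samples} animals x {cohort.n_snps} SNPs "
      f"({config.n_chromosomes} chromosomes)")
print(f"implanted truth events: {len(cohort.truth)}")
for ev in cohort.truth[:5]:
    kb = ev.length_bp / 1000
    kind = "deletion" if ev.copy_number < 2 else "duplication"
    print(f"  {ev.sample_id}  chr{ev.chromosome}:{ev.start_bp}-{ev.end_bp}"
          f"  CN={ev.copy_number} ({kind}, {kb:.0f} kb)")

paths = oc.simulate.write_cohort(cohort, "scratch/example_cohort")
print(f"\nwrote PennCNV-style signals, PFB, PLINK PED/MAP and the truth set "
      f"under scratch/example_cohort ({len(paths['signals'])} signal files)")
print("each truth event perturbs LRR toward its copy-number state mean and "
      "moves BAF clusters to k/c - exactly what the caller must undo.")
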