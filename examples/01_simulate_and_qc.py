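"""Simulate a cohort and run SNP-level quality control.

The cohort has 600 individuals, 50 SNPs (one of them driving the first
expression module), 180 probes in three planted modules of 50 plus 30 noise
probes, and a blood-pressure-like trait observed at three visits.
"""
import numpy as np

from triocausal import CohortSpec, simulate_cohort, snp_qc

spec = CohortSpec(n=600, n_snps=50, maf=[0.005] * 2 + [0.3] * 48, seed=1)
genotypes, expression, phenotypes, truth = simulate_cohort(spec)

print(f"genotypes:  {genotypes.n_samples} individuals x {genotypes.n_snps} SNPs")
print(f"expression: {expression.n_samples} individuals x {len(expression.probe_ids)} probes")
print(f"phenotype records: {len(phenotypes.data)} "
      f"({phenotypes.data['time_point'].nunique()} visits per individual)")
print(f"planted causal SNP: {truth['causal_snp']} -> module {truth['causal_module']}"
      f" -> trait {truth['trait']} (coupling {truth['coupling']})")

filtered, report = snp_qc(genotypes, maf_min=0.01, miss_max=0.05)
print(f"\nQC removed {report['removed_maf']} SNPs below MAF 1% and "
      f"{report['removed_missingness']} for missingness; "
      f"{report['n_retained']} of {report['n_input']} retained.")
# The two SNPs simulated at MAF 0.5% are the ones the frequency filter drops.
print("folded MAF of retained SNPs: "
      f"min {filtered.maf().min():.3f}, max {filtered.maf().max():.3f}")
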