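"""Two-stage association filtering from a full cohort down to trios.

Stage 1 scans probes against the adjusted phenotype; stage 2 scans every SNP
against each passing probe's expression. Pairs with -log10 p > 5 at both
stages become the trios taken into causal modelling.
"""
from triocausal import (
    CohortSpec, adjust_phenotype, align_samples, correct_for_sex,
    probe_phenotype_scan, select_trios, simulate_cohort, snp_probe_gwas, snp_qc,
)

spec = CohortSpec(n=600, n_snps=40, n_probes=30, module_sizes=(10,),
                  loadings=0.95, coupling=0.5, seed=3)
genotypes, expression, phenotypes, truth = simulate_cohort(spec)
genotypes, _ = snp_qc(genotypes)
adjusted = adjust_phenotype(phenotypes, "SBP",
                            ("age", "sex", "medication", "smoking"))
genotypes, expression, y = align_samples(genotypes, expression, adjusted)
expression = correct_for_sex(expression, phenotypes.sex_by_individual())

probe_scan = probe_phenotype_scan(expression, y.to_numpy())
print("top of the probe~phenotype scan (-log10 p):")
print(probe_scan.table.head(3)[["id", "beta", "mlog10p"]].to_string(index=False))

passing = list(probe_scan.passing(5.0)["id"])
print(f"\n{len(passing)} probes pass -log10 p > 5")

gwas = {pid: snp_probe_gwas(genotypes, expression.probe_vector(pid))
        for pid in passing}
trios = select_trios(probe_scan, gwas, 5.0, genotypes=genotypes,
                     expression_vectors={p: expression.probe_vector(p)
                                         for p in passing},
                     phenotype=y.to_numpy(), phenotype_name="SBP",
                     sample_ids=genotypes.sample_ids)
print(f"{len(trios)} trios formed; SNPs involved: "
      f"{sorted({t.snp_id for t in trios})}")
print(f"planted causal SNP was {truth['causal_snp']}: the filter recovered "
      "exactly the planted chain." if {t.snp_id for t in trios} ==
      {truth["causal_snp"]} else "note: extra or missing SNPs this draw.")
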