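"""Build the working phenotype: covariate residuals averaged over visits.

At each visit the trait is regressed on age, sex, medication and smoking;
the per-individual average of the residuals is the phenotype used by every
downstream stage. Removing covariate variance makes the planted genetic
signal visible: the adjusted trait correlates with the module factor far
more strongly than the raw visit average does.
"""
import numpy as np

from triocausal import CohortSpec, adjust_phenotype, simulate_cohort

spec = CohortSpec(n=600, coupling=0.5, seed=2)
_, _, phenotypes, truth = simulate_cohort(spec)

adjusted = adjust_phenotype(phenotypes, "SBP",
                            ("age", "sex", "medication", "smoking"))
print(f"adjusted phenotype for {adjusted.series.size} individuals; "
      f"mean {adjusted.series.mean():.3e} (residuals are centred)")

factor = np.array(truth["factors"])[:, truth["causal_module"]]
ids = sorted(adjusted.series.index)
raw = (phenotypes.data[phenotypes.data.trait == "SBP"]
       .groupby("individual_id")["value"].mean().loc[ids])
r_raw = np.corrcoef(raw, factor)[0, 1]
r_adj = np.corrcoef(adjusted.series.loc[ids], factor)[0, 1]
print(f"correlation with planted module factor: raw visit mean r = {r_raw:.3f}, "
      f"adjusted phenotype r = {r_adj:.3f}")
print("covariate adjustment strips age/sex/medication/smoking variance, "
      "so the genetic component stands out.")
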