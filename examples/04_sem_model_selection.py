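"""Structural-equation model selection over the 12 admissible trio DAGs.

Data are simulated under mediation (b): SNP -> GE -> PHEN with effects 0.5.
Each DAG is fitted as a recursive linear Gaussian system; AIC = 2k - 2logL
picks the most plausible topology. The two Markov-equivalent 3-edge DAGs
always share an AIC — ties like that are reported, never hidden.
"""
from triocausal import TrioSpec, select_sem, simulate_trio
from triocausal.filtering import Trio

s, g, p = simulate_trio(TrioSpec.for_dag("(b)", 0.5, n=1000, seed=4))
trio = Trio("rs1", s, "probe0", g, "SBP", p, tuple(f"i{k}" for k in range(1000)))

result = select_sem(trio, "all")
table = result.table.sort_values("aic")[["label", "log_likelihood", "n_params", "aic"]]
print(table.to_string(index=False, float_format=lambda v: f"{v:.2f}"))
print(f"\nselected: {result.selected} (tie set: {result.tie_set})")
print("the generating mediation model (b) attains the lowest AIC; "
      "the two 3-edge DAGs above it differ only by a wasted parameter.")
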