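"""Bayes-factor partition selection, and its collider blind spot.

The Bayesian framework partitions {GE, PHEN} into (Unassociated, Directly,
Indirectly associated) with the SNP and scores each partition with a closed-
form Bayes factor against the all-U null. On mediation data it picks
D={GE}, I={PHEN}, i.e. model (b). On collider data SNP -> GE <- PHEN it has
no matching partition and calls (f), while the SEM menu recovers (d) —
the two methods disagree there by construction.
"""
from triocausal import TrioSpec, select_buf, select_sem, simulate_trio
from triocausal.filtering import Trio


def trio_under(label, seed, effect):
    s, g, p = simulate_trio(TrioSpec.for_dag(label, effect, n=1000, seed=seed))
    return Trio("rs1", s, "probe0", g, "SBP", p,
                tuple(f"i{k}" for k in range(1000)))


mediation = trio_under("(b)", 5, 0.8)
res = select_buf(mediation)
print("log10 Bayes factors under mediation data:")
print(res.table.to_string(index=False, float_format=lambda v: f"{v:.2f}"))
print(f"selected: {res.selected.name} -> model {res.model} "
      f"(margin {res.margin:.2f} log10 units"
      f"{', near-tie flagged' if res.near_tie else ''})")

from collections import Counter

buf_calls, sem_calls = Counter(), Counter()
for rep in range(100):
    collider = trio_under("(d)", 600 + rep, 0.5)
    buf_calls[select_buf(collider).model] += 1
    sem_calls[select_sem(collider).selected] += 1
print(f"\n100 collider replicates (SNP -> GE <- PHEN, effects 0.5, n = 1000):")
print(f"  BUF calls: {dict(buf_calls.most_common())}")
print(f"  SEM calls: {dict(sem_calls.most_common())}")
print("the partition framework cannot express 'phenotype influences "
      "expression independently of the SNP', so it mostly reports (f); "
      "the SEM menu tests (d) directly and mostly recovers it.")
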