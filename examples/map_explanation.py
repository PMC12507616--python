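"""MAP genotype-combination search: which 9-locus genotype best explains
disease?

Fits CPTs on a simulated cohort, clamps the disease node to "case", and
exhaustively enumerates all 3^9 = 19,683 genotype combinations over the nine
modeled loci, ranking them by P(combination | disease). The top entry is the
maximum a-posteriori explanation; alongside it the model reports
P(disease | combination) — how risky that genotype pattern is on its own.
"""

import snpbn as s
from snpbn.discrete import DISEASE_NODE

spec = s.default_scenario()
ds, truth = s.simulate(spec)
cpts = s.fit_cpts_available_case(truth.structure, ds)

result = s.map_search(cpts, evidence_state=1)
print(f"enumerated {result.n_enumerated} genotype combinations "
      f"(posteriors sum to {result.posterior.sum():.12f})\n")

loci = result.loci
print("top 5 combinations given disease = case:")
for k in range(5):
    combo = {l: int(st) for l, st in zip(loci, result.states[k])}
    labels = [s.table1_locus(l).state_labels[combo[l]] for l in loci]
    print(f"  #{k + 1}: P(combo|case) = {result.posterior[k]:.5f}   "
          f"P(case|combo) = {result.disease_given_combo[k]:.4f}")
    print("      " + " ".join(f"{l}={g}" for l, g in zip(loci, labels)))

prior = s.predict_disease(cpts, {})
top = result.top()
print(f"\nbaseline disease probability (no evidence): {prior:.4f}")
print(f"disease probability under the MAP combination: "
      f"{s.predict_disease(cpts, top):.4f}")
print("\nThe MAP combination concentrates every locus on its highest-risk"
      "\ngenotype consistent with the learned dependencies; the jump from the"
      "\nbaseline quantifies how much the joint genotype pattern matters.")
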