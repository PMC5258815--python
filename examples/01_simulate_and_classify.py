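"""Generate a synthetic CAMR cohort and call the ELISPOT phenotypes.

The generator emits the three cohort tables (patients, eGFR series, ELISPOT
spot counts) plus the latent ground truth; the classifier turns each
sample's four depletion-condition counts into a positivity quadruple, a
fine pattern and a four-way functional category.
"""

from collections import Counter

import camrspot as cs

cohort, truth = cs.generate_cohort(cs.scenario_paper(), seed=1)
print(f"cohort: {cohort.n_patients} patients "
      f"({sum(p.subgroup.value == 'PROTCL' for p in cohort.patients)} protocol, "
      f"{sum(p.subgroup.value == 'BFC' for p in cohort.patients)} for-cause)")

calls = cs.classify_cohort(cohort)
counts = Counter(
    (tp.value, c.coarse_category.value)
    for (_, tp, _), c in calls.items()
    if c.interpretable
)
print("\ninterpretable donor samples per functional category:")
for (tp, cat), n in sorted(counts.items()):
    print(f"  {tp}  {cat:<22} {n}")
print("\nCounts mirror the published time-point-1 tallies (8, 5, 12, 13 of 38"
      "\ninterpretable samples); nonviable samples carry no call.")
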