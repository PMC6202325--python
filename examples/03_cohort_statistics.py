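"""Prevalence and mutual-exclusivity statistics from cohort counts.

Reconstructs the kind of 2x2 tables a fusion study reports: fusion
positivity vs driver-mutation status in the sequenced subset.  A zero
count in the fusion-positive/mutated cell with a significant uncorrected
chi-square indicates mutual exclusivity — the fusion and the mutation
appear to be alternative routes to the same phenotype.
"""

from dgcfusion import TwoByTwo, chi_square_2x2, fisher_exact_2x2
from dgcfusion.cohort import round_percent

# 17 of 384 tumors carry one of three recurrent in-frame fusions
print(f"fusion prevalence: 17/384 = {round_percent(17, 384)}%")

# sequenced subset: 17 fusion-positive (0 CDH1-mutated),
# 212 fusion-negative (66 CDH1-mutated)
cdh1 = TwoByTwo(a=0, b=17, c=66, d=146)
stat, _, p = chi_square_2x2(cdh1)
print(f"CDH1 mutations among fusion-negative: 66/212 = {round_percent(66, 212)}%")
print(f"fusion vs CDH1 chi-square = {stat:.2f}, P = {p:.3f} "
      "(uncorrected; mutual exclusivity)")

rhoa = TwoByTwo(a=0, b=17, c=32, d=180)
stat, _, p = chi_square_2x2(rhoa)
print(f"fusion vs RHOA chi-square = {stat:.2f}, P = {p:.2f} (trend)")

# early-onset (8/135) vs late-onset (5/249) prevalence of the most
# common fusion
onset = TwoByTwo(a=8, b=127, c=5, d=244)
stat, _, p = chi_square_2x2(onset)
print(f"early vs late onset: chi-square = {stat:.2f}, P = {p:.3f}; "
      f"Fisher P = {fisher_exact_2x2(onset):.3f}")
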