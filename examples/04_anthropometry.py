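"""Anthropometry: z-score bands and mortality relative risks.

A stunting prevalence pins down a unit-SD normal shifted against the
international growth standard; band occupancies below -3, -3..-2,
-2..-1 and above -1 SD follow from the normal CDF.  Weighting each
band's relative risk of death by its occupancy gives the average
relative risk (ARR); the mortality reduction between two years is
1 - ARR_t / ARR_0.
"""

import childimpact as ci

baseline = ci.prevalence_to_bands(0.35)
improved = ci.prevalence_to_bands(0.30)
labels = ("< -3 SD", "-3..-2 SD", "-2..-1 SD", ">= -1 SD")
print("band occupancy at 35% vs 30% stunting:")
for label, b0, b1 in zip(labels, baseline.fractions, improved.fractions):
    print(f"  {label:>10}: {100 * b0:5.1f}% -> {100 * b1:5.1f}%")

rr = (4.6, 2.1, 1.4, 1.0)  # e.g. diarrhoea mortality, children 1-5 months
arr0 = ci.average_relative_risk(baseline, rr)
arr1 = ci.average_relative_risk(improved, rr)
reduction = ci.mortality_reduction_from_arr(arr1, arr0)
print(f"average relative risk {arr0:.3f} -> {arr1:.3f}: "
      f"a {100 * reduction:.1f}% diarrhoea-mortality reduction")

# Supplemental feeding moves severely wasted children (< -3 SD weight
# for height) into better bands; mass is conserved.
wasting = ci.prevalence_to_bands(0.06, anchor_cut=-3.0)
after = ci.apply_supplemental_feeding(
    wasting, coverage_change=0.5, destination_split=(0.2, 0.3, 0.3, 0.2)
)
print(f"severe wasting {100 * wasting.below_minus3:.1f}% -> "
      f"{100 * after.below_minus3:.1f}% after supplemental feeding at 50% coverage")
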