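"""Generate a synthetic postpartum-screening cohort and inspect it.

Builds a 10-item, 4-category response table for 5,000 patients with a
realistic demographic mix, then prints the positive-screen rate
(total >= 8 or suicidal-ideation endorsement) and the suicidal-ideation
endorsement rate.  The expected positive rate is ~11-12%, matching a
routine postpartum screening program.
"""

from epdscat import CohortSpec, generate_cohort

spec = CohortSpec(n=5000, dimension=1, seed=7)
cohort = generate_cohort(spec)

items = [f"item{i}" for i in range(1, 11)]
totals = cohort[items].sum(axis=1)
si = cohort["item10"]
positive = (totals >= 8) | (si > 0)

print(cohort.head())
print(f"\npositive-screen rate: {positive.mean():.1%}")
print(f"suicidal-ideation endorsement: {(si > 0).mean():.1%}")
print(f"mean total score: {totals.mean():.2f} (scale 0-30)")
print(cohort["race"].value_counts(normalize=True).round(3))
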