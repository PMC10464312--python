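"""Descriptive survival on the age timescale with delayed entry.

Left truncation matters: subjects enter the risk set at their age at
survey, so the curves are survival as a function of *age*, estimated
from staggered entries, and the group medians are median survival ages.
"""

import medhaz as mh

cohort = mh.generate_cohort(mh.default_params(n=30_000), seed=3)
curves = mh.km_left_truncated(cohort, group_by=("sex", "race_ethnicity"))
print("median survival age (95% CI):")
for key, curve in sorted(curves.items()):
    med, (lo, hi) = mh.median_survival_age(curve)
    print(f"  {' '.join(key):14s} {med:5.1f}  ({lo:5.1f}, {hi:5.1f})")

tab = mh.prevalence_table(cohort)
cols = ["sex", "race_ethnicity", "n", "person_years", "deaths", "deaths_pct"]
print("\nfollow-up summary:")
print(tab[cols].round(1).to_string(index=False))
print("\nMedians in the mid-70s to low-80s with lower values for the "
      "higher-hazard group mirror the age-timescale reading: these are "
      "ages, not follow-up durations.")
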