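"""Derive version-specific variables from trial histories.

Degree of enrollment anchors the anticipated figure to the first record
version on/after the trial's start date and the actual figure to the last
version marked actual; trial days come from the version where the status
first became terminated.
"""

from termtrials import CohortConfig, generate_cohort, derive_variables
from termtrials.derivation import aggregate_degree_of_enrollment

cohort = generate_cohort(CohortConfig(seed=1, n_trials=200, terminated_fraction=1.0,
                                      other_status_fraction=0.0))
derived = [derive_variables(h) for h in cohort.histories]

d = derived[0]
print(f"{d.trial_id}: anticipated={d.anticipated_enrollment}, "
      f"actual={d.actual_enrollment}, degree={d.degree_of_enrollment_pct:.1f}%, "
      f"trial_days={d.trial_days}")
# per-trial ratio of achieved to planned enrollment, and days to termination

agg = aggregate_degree_of_enrollment(derived)
print(f"aggregate degree of enrollment: {agg.pct:.1f}% "
      f"(= {agg.total_actual}/{agg.total_anticipated}, rounded {agg.pct_rounded}%)")
# the cohort-level figure is the ratio of summed totals, not a mean of ratios
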