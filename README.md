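# termtrials

Characterize prematurely **terminated clinical trials** from versioned
registry records. Registries such as ClinicalTrials.gov keep every dated
edit of a trial's entry; several variables that matter for studying
termination are only visible in that version history, not in a single
download:

- **Degree of enrollment** — actual enrollment as a percentage of the
  planned figure: `100 × actual / anticipated`, where *anticipated* is read
  from the first record version on or after the trial's start date and
  *actual* from the latest version marked actual. Over-enrollment (>100%)
  is possible. The cohort-level figure is the ratio of summed totals,
  `100 × Σ actual / Σ anticipated`.
- **Trial days** — days from start to stop, where the stop date is the
  primary completion date in force in the version where the overall status
  *first* became "terminated", and the start date comes from that same
  version.
- **Termination reason** — the 160-character `why_stopped` free text,
  classified by an auditable keyword/regex rule table into a 12-category
  taxonomy (scientific: futility, external evidence, harm, unspecified
  interim evidence, benefit; non-scientific: low accrual, funding, PI
  departure, investigational-product supply, administrative/logistical/
  technical; plus "reason not provided" and "other"). When a text names
  both classes, the scientific reason is primary. Rater agreement is
  quantified with Cohen's kappa, `κ = (p_o − p_e) / (1 − p_e)`.
- **Therapeutic focus** — each MeSH condition term's tree numbers are
  truncated to their top-level code (e.g. `C04.588.180 → C04`, Neoplasms);
  a trial's foci are the deduplicated union over its terms, tabulated by
  occurrence across the cohort.
- **SAE risk meta-analysis** — trials terminated for non-scientific
  reasons with tabular summary results and a parallel randomized two-arm
  design (an ordered eligibility cascade attributes every exclusion to the
  first failing filter) are collapsed to 2×2 tables of participants with
  ≥1 serious adverse event, intervention vs control. Per-trial risk
  ratios are pooled on the log scale: inverse-variance common-effect
  (`w_i = 1/se_i²`) and DerSimonian–Laird random-effects
  (`w*_i = 1/(se_i² + τ̂²)`), with Cochran's Q, τ², and
  `I² = max(0, (Q − (k−1))/Q) × 100`, 0.5 continuity correction for
  single-zero tables, and z-based 95% CIs.

Everything is testable offline: a seeded **synthetic registry generator**
produces version histories, designs, MeSH terms, arm-level SAE tables and
a ground-truth record with the statistical structure the analysis assumes
(no network access, no registry scraping).

Intended users: meta-researchers and clinical-trial transparency groups
working with registry version histories.

## Worked example

```python
from termtrials import (
    generate_cascade_fixture, derive_variables, classify_reason,
    CascadeRecord, eligibility_cascade, build_two_by_two, study_effect,
    pool_common_effect, pool_random_effects,
)

fx = generate_cascade_fixture()          # deterministic 76-trial fixture
designs = {d.trial_id: d for d in fx.designs}
records = [
    CascadeRecord(h.trial_id,
                  classify_reason(h.final_version.why_stopped).primary_class,
                  derive_variables(h).summary_results,
                  h.euctr_results_tabular, designs[h.trial_id])
    for h in fx.histories
]
elig = eligibility_cascade(records)
print(elig.exclusions, len(elig.included_trial_ids))
```

prints

```
{'single_arm': 30, 'active_comparator': 20, 'non_randomized': 7,
 'crossover': 2, 'no_intervention_administered': 2,
 'non_tabular_cross_registry': 1, 'metadata_missing': 0} 14
```

— of 76 terminated-for-non-scientific-reasons trials with summary results,
61 fail a design filter, 1 has cross-registry results only as a PDF, and 14
enter the meta-analysis. Pooling their (synthetic, null-generated) SAE
tables:

```
common_effect:  RR 1.0412 [0.8334; 1.3009], p = 0.7223, I^2 = 0.0%
random_effects: RR 1.0412 [0.8334; 1.3009], p = 0.7223, I^2 = 0.0%
```

a risk ratio near 1 with a CI spanning 1: no detectable excess SAE risk in
the intervention arms. The `examples/` directory has one short script per
capability (simulation, derivation, reason classification, focus mapping,
meta-analysis, full pipeline), and the `termtrials` CLI exposes the same
stages as subcommands (`simulate`, `validate`, `derive`, `classify`,
`foci`, `cascade`, `meta`, `run`).

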