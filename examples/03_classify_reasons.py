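"""Classify free-text termination reasons and tabulate the taxonomy.

The rule table maps 160-character `why_stopped` texts to a 12-category
taxonomy; when a text names both a scientific and a non-scientific reason,
the scientific one is primary.
"""

from termtrials import classify_reason, tabulate_reasons

texts = [
    "Terminated due to slow accrual",
    "Stopped for futility after interim analysis; recruitment was also slow",
    "Protocol modification",
    "",
]
assignments = [classify_reason(t, f"NCT{i}") for i, t in enumerate(texts)]
for t, a in zip(texts, assignments):
    print(f"{t!r:72s} -> {a.primary_category} ({a.primary_class})")
# the dual-reason text resolves to the scientific clause (futility), the
# vague text to 'other', the empty text to 'reason_not_provided'

table = tabulate_reasons(assignments)
print(table[["cohort_n", "cohort_pct"]])
# counts and within-cohort percentages, with class subtotals and a total row
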