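# Methods

## Scope and data model

The package analyzes *versioned* registry records. A trial is represented
as a `TrialHistory`: a strictly ordered sequence of `TrialVersion`
snapshots keyed by `(version_date, version_seq)`, plus trial-level
cross-registry (EUCTR-style) results flags. Ordering is enforced on
construction, so every derivation is invariant to input row order. On disk
a cohort is one long-format CSV (one row per version) plus an optional
trial-attributes CSV; unparseable rows or fields go to a rejects report,
never silently dropped. Month-precision dates are completed to the first of
the month and flagged; status strings are normalized through a fixed
synonym table, with unrecognized strings mapped to `other` and flagged.

## Variable derivation

**Degree of enrollment.** Anticipated enrollment is the figure in the
earliest version dated on or after the trial's start date whose enrollment
is marked anticipated; a figure present but unmarked is accepted as
anticipated and flagged (`unmarked_assigned_anticipated`). The start date
used for this comparison is taken from the first version carrying any start
date; if no version is dated on/after it, the earliest anticipated-type
figure is used and flagged (`no_version_on_or_after_start`) — derivation
warns rather than fails. Actual enrollment is the figure in the *latest*
version marked actual (not necessarily the final version, so
post-termination administrative edits without enrollment data do not erase
it). The per-trial degree is `100 × actual / anticipated` when both exist
and anticipated > 0; otherwise it is missing with flags, including
`excluded_unclear_enrollment`. The cohort aggregate is the ratio of summed
totals over usable trials (both the unrounded value and the count of
excluded trials are reported, so either the over-all or over-usable
convention can be quoted).

**Trial days.** The stop date is the primary completion date recorded in
the version where the overall status first became terminated; the start
date comes from that same version, and later versions are never consulted
even if they carry a missing date. Negative differences (registry
data-entry errors) become missing plus a `negative_duration` flag rather
than negative durations. The variable is defined only for terminated
trials.

**Summary results.** Availability is read off the final version; a flag
that appeared in an earlier version but is absent from the final one does
not count (the final-version rule is applied literally). Trials without
registry summary results but with cross-registry results are classed
`euctr_only`.

## Reason classification

Classification is a pure function of the text: case-insensitive,
whitespace-normalization invariant, driven by an ordered keyword/regex rule
table shipped as a plain CSV (`data/reason_rules.csv`) so it can be audited
and extended. Empty text → `reason_not_provided`; text matching no rule →
`other` (vague texts such as "Protocol modification" land here). Every
matching category is recorded with its earliest character position;
the primary category is resolved by scientific primacy (any scientific
match beats every non-scientific one) and, within a class, by order of
mention. Cohen's kappa is computed from the marginal label distributions
(`κ = (p_o − p_e)/(1 − p_e)`), on the full 12-category labels; perfect
agreement is κ = 1 even at the `p_e = 1` boundary. The rule table was
written against the category names of the taxonomy and the template corpus
in `synthetic.py`; templates and rules are co-designed so that template
texts define the classifier's required recall set. Real free text is more
varied than the templates — see *Limitations*.

## Therapeutic-focus mapping

A "high-level category" is operationalized as the first dot-segment of a
MeSH tree number (e.g. `C04` → Neoplasms), matching top-of-branch headings.
The lookup is a local term → tree-number table (network-free); terms may
carry numbers under several branches and then contribute several foci.
Per-trial foci are deduplicated sets; trials with no submitted terms and
trials whose terms all fail to resolve are both "unassigned", flagged
distinctly. Tabulation counts occurrences (Σ per-trial set sizes), and the
percentage denominator includes one occurrence per unassigned trial — the
alternative (excluding them) is an option. Collapsing minor categories into
"Miscellaneous" is a reporting option, not part of the mapping. No attempt
is made to pick a single most-relevant focus per trial.

## SAE eligibility cascade and meta-analysis

Candidates are terminated trials whose primary reason class is
non-scientific; of those with summary results available, filters apply in
fixed order — single-arm, active comparator, non-randomized, crossover, no
participant received an intervention, cross-registry-only results not in
structured tabular form — and each excluded trial is attributed to the
first filter it fails (PRISMA-style counts). Candidates with missing design
metadata go to a `metadata_missing` bucket, never silently included.

Arms are collapsed to a 2×2 using a *manual* arm-role annotation table;
registry arm identifiers are never trusted as roles. Multiple intervention
arms are summed into one column; exactly one control arm is required; a
role of `other` makes the trial ineligible rather than guessed.

Per-trial effects: `RR = (a/n1)/(c/n2)`,
`se(log RR) = √(1/a − 1/n1 + 1/c − 1/n2)`, risk difference on uncorrected
counts. Sparse data: 0.5 added to each of the four cells when exactly one
event cell is zero; double-zero trials are excluded from RR pooling (their
RD is retained). Pooling: generic inverse-variance common-effect estimator
on log RR (Mantel–Haenszel offered as an alternative, since software
defaults for binary data differ); DerSimonian–Laird τ² for random effects
(REML exposed as an option); Cochran's Q and I² truncated at zero; 95%
z-based (Wald) intervals, not Knapp–Hartung. With τ̂² = 0 the
random-effects result equals the common-effect result component-wise.

## Synthetic generator

The generator emulates the cohort structure the analysis assumes, with one
seed split hierarchically per trial (`SeedSequence.spawn`), so adding
trials never perturbs earlier ones and equal seeds give byte-identical
outputs. Defaults (chosen once, from published cohort statistics where
available):

| parameter | default | rationale |
|---|---|---|
| terminated fraction | 0.10 | ~10% of registry cohorts are terminated |
| other-status fraction | 0.05 | withdrawn/suspended/unknown trials to exercise exclusion |
| reason mix | pooled taxonomy counts / 367 | observed composition; low accrual ≈48% |
| dual-reason probability | 9/367 | observed frequency of dual-reason texts |
| anticipated enrollment | log-normal, median 80, σ=1.0 | matches published median and IQR spread |
| attainment, terminated | Gamma(2, 0.195), mean 0.39 | aggregate degree ≈39%; ~8% of trials exceed 100% |
| attainment, completed | Gamma(12, 0.08), mean 0.96 | completed trials nearly reach plan |
| duration | log-normal, median 1000 days, σ=0.6 | published median ~1,000 days |
| summary-results prob. | 0.29 terminated / 0.10 completed | published registry-reporting rates |
| publication prob. | 0.32 / 0.77 | published publication rates |
| SAE: true log RR, τ | 0.0, 0.2 | null intervention effect with moderate heterogeneity |
| SAE: control risk | Beta(2, 8) | serious-event risks centered near 20% |
| SAE: arm size | log-normal, median 50/arm | small trials typical of terminated studies |

Corruption knobs (missing actual enrollment, unmarked enrollment type,
missing reason text) are separate probabilities, off by default; with them
off, generated histories validate cleanly.

What the generator does **not** emulate: real NCT numbering semantics, the
breadth of real MeSH coverage, free-text diversity beyond the
classifier-exercising templates, intermediate enrollment updates, or
correlations between design features and termination reasons. Passing
tests therefore demonstrate correctness of the derivations, classifier
mechanics, mapping and pooling arithmetic on data with known structure —
not classifier recall on real registry prose.

The deterministic 76-trial cascade fixture encodes the published exclusion
composition exactly (30 single-arm, 20 active comparator, 7 non-randomized,
2 crossover, 2 without intervention, 1 cross-registry PDF-only, 14 eligible
of which 3 cross-registry tabular); its SAE counts are generated under a
null effect from a fixed internal seed.

## Numerical conventions

- Percentages are rounded half away from zero to integers, with one
  decimal below 1% (so 2/217 prints "0.9").
- Medians and IQRs use linear interpolation between order statistics
  (the mainstream numerical-stack default); documented because quantile
  conventions change printed values.
- Heterogeneity: τ² and I² truncated at 0; k < 2 gives Q = τ² = I² = 0 by
  convention.
- Quantities reported by `scripts/acceptance.py` use moderate problem
  sizes (217-trial enrollment split, 367-trial reason composition,
  400-trial synthetic cohort for classifier checks) — large enough for the
  count/percentage outputs to be exact or seed-invariant.
- The run log contains no timestamps, so identical configs produce
  byte-identical output trees.

## Known limitations

- The rule table is an implementation informed by the taxonomy's category
  names and common registry phrasing, not a transcript of any manual
  coding sheet; on real free text its accuracy is untested and it cannot
  distinguish business from scientific drivers hidden behind phrases like
  "slow accrual".
- Pooled SAE estimates from real cohorts depend on registry counts that
  are not published; the package validates its pooling arithmetic against
  independent oracles and parameter-recovery simulations instead.
- Whether a results flag that appears then disappears across versions
  should count as "available" is ambiguous in registry practice; the
  final-version rule is applied literally.
- The snapshot date of a history download is the caller's responsibility;
  the package does not model it.
- No imputation of missing enrollment, no use of participant-flow counts
  as enrollment, no publication search, no network access of any kind.
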