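"""Version-specific variable derivation from trial histories.

Three variables are derived per trial, each anchored to a specific version
of the record rather than the latest download:

* **Degree of enrollment** — actual enrollment as a percentage of the
  anticipated (planned) figure. Anticipated is read from the first version
  on or after the trial's start date whose enrollment is marked anticipated
  (a number present but unmarked is accepted as anticipated and flagged);
  actual is the latest version marked actual. The ratio can exceed 100%
  (trials do over-enroll).
* **Trial days** — days from start to stop, where the stop date is the
  primary completion date in force in the version where the status *first*
  became terminated, and the start date comes from that same version.
  Defined only for terminated trials.
* **Summary-results availability** — read off the final version; a trial
  without registry summary results may still have cross-registry (EUCTR)
  results, tracked as ``euctr_only``.

Missing or unclear data never raises: it yields missing values plus
machine-readable provenance flags.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import pandas as pd

from ._util import round_half_away
from .registry import EnrollmentType, OverallStatus, TrialHistory

FLAG_NO_ACTUAL = "no_actual"
FLAG_NO_ANTICIPATED = "no_anticipated"
FLAG_UNMARKED_ASSIGNED = "unmarked_assigned_anticipated"
FLAG_EXCLUDED_UNCLEAR = "excluded_unclear_enrollment"
FLAG_NO_TERMINATED_VERSION = "no_terminated_version"
FLAG_NEGATIVE_DURATION = "negative_duration"
FLAG_NO_VERSION_ON_OR_AFTER_START = "no_version_on_or_after_start"


@dataclass
class DerivedVariables:
    """Per-trial derived variables with provenance flags."""

    trial_id: str
    anticipated_enrollment: Optional[int] = None
    actual_enrollment: Optional[int] = None
    degree_of_enrollment_pct: Optional[float] = None
    trial_days: Optional[int] = None
    stop_date: Optional[dt.date] = None
    start_date_used: Optional[dt.date] = None
    summary_results: str = "none"  # ctgov | euctr_only | none
    flags: set[str] = field(default_factory=set)


@dataclass
class AggregateEnrollment:
    """Cohort-level degree of enrollment: 100 × Σ actual / Σ anticipated
    over trials where both figures exist (the sum-ratio, not the mean of
    per-trial ratios)."""

    total_anticipated: int
    total_actual: int
    pct: Optional[float]
    pct_rounded: Optional[int]
    n_usable: int
    n_excluded: int


def derive_degree_of_enrollment(history: TrialHistory) -> DerivedVariables:
    """Derive anticipated/actual enrollment and their ratio for one trial."""
    d = DerivedVariables(trial_id=history.trial_id)

    start_anchor: Optional[dt.date] = None
    for v in history.versions:
        if v.start_date is not None:
            start_anchor = v.start_date
            break

    candidates = [
        v
        for v in history.versions
        if v.enrollment_count is not None
        and v.enrollment_type in (EnrollmentType.anticipated, EnrollmentType.unmarked)
    ]
    selected = None
    if candidates:
        if start_anchor is not None:
            on_or_after = [v for v in candidates if v.version_date >= start_anchor]
            if on_or_after:
                selected = on_or_after[0]
        if selected is None:
            # no version dated on/after the start (or no start date at all):
            # fall back to the earliest anticipated-type figure and flag it
            selected = candidates[0]
            d.flags.add(FLAG_NO_VERSION_ON_OR_AFTER_START)
    if selected is not None:
        d.anticipated_enrollment = selected.enrollment_count
        if selected.enrollment_type == EnrollmentType.unmarked:
            d.flags.add(FLAG_UNMARKED_ASSIGNED)
    else:
        d.flags.add(FLAG_NO_ANTICIPATED)

    actuals = [v for v in history.versions if v.enrollment_type == EnrollmentType.actual]
    if actuals:
        d.actual_enrollment = actuals[-1].enrollment_count
    else:
        d.flags.add(FLAG_NO_ACTUAL)

    if (
        d.anticipated_enrollment is not None
        and d.anticipated_enrollment > 0
        and d.actual_enrollment is not None
    ):
        d.degree_of_enrollment_pct = 100.0 * d.actual_enrollment / d.anticipated_enrollment
    else:
        d.flags.add(FLAG_EXCLUDED_UNCLEAR)
    return d


def aggregate_degree_of_enrollment(derived: Sequence[DerivedVariables]) -> AggregateEnrollment:
    """Aggregate degree of enrollment over a cohort as the ratio of summed
    totals, over trials where both anticipated and actual are present."""
    if not derived:
        raise ValueError("empty collection")
    usable = [
        d
        for d in derived
        if d.anticipated_enrollment is not None
        and d.anticipated_enrollment > 0
        and d.actual_enrollment is not None
    ]
    total_ant = sum(d.anticipated_enrollment for d in usable)
    total_act = sum(d.actual_enrollment for d in usable)
    if not usable or total_ant == 0:
        return AggregateEnrollment(0, 0, None, None, 0, len(derived))
    pct = 100.0 * total_act / total_ant
    return AggregateEnrollment(
        total_anticipated=total_ant,
        total_actual=total_act,
        pct=pct,
        pct_rounded=int(round_half_away(pct)),
        n_usable=len(usable),
        n_excluded=len(derived) - len(usable),
    )


def derive_trial_days(history: TrialHistory) -> DerivedVariables:
    """Derive the start→stop duration from the version where the status
    first became terminated; later versions are never consulted, even if
    they carry the missing date."""
    d = DerivedVariables(trial_id=history.trial_id)
    first_terminated = None
    for v in history.versions:
        if v.overall_status == OverallStatus.terminated:
            first_terminated = v
            break
    if first_terminated is None:
        d.flags.add(FLAG_NO_TERMINATED_VERSION)
        return d
    d.stop_date = first_terminated.primary_completion_date
    d.start_date_used = first_terminated.start_date
    if d.stop_date is not None and d.start_date_used is not None:
        days = (d.stop_date - d.start_date_used).days
        if days < 0:
            d.flags.add(FLAG_NEGATIVE_DURATION)
        else:
            d.trial_days = days
    return d


def derive_summary_results(history: TrialHistory) -> DerivedVariables:
    """Summary-results availability from the final version, falling back to
    cross-registry (EUCTR) availability."""
    d = DerivedVariables(trial_id=history.trial_id)
    if history.final_version.has_summary_results:
        d.summary_results = "ctgov"
    elif history.euctr_results_available:
        d.summary_results = "euctr_only"
    else:
        d.summary_results = "none"
    return d


def derive_variables(history: TrialHistory) -> DerivedVariables:
    """All per-trial derivations merged into one record."""
    enr = derive_degree_of_enrollment(history)
    dur = derive_trial_days(history)
    res = derive_summary_results(history)
    return DerivedVariables(
        trial_id=history.trial_id,
        anticipated_enrollment=enr.anticipated_enrollment,
        actual_enrollment=enr.actual_enrollment,
        degree_of_enrollment_pct=enr.degree_of_enrollment_pct,
        trial_days=dur.trial_days,
        stop_date=dur.stop_date,
        start_date_used=dur.start_date_used,
        summary_results=res.summary_results,
        flags=enr.flags | dur.flags | res.flags,
    )


def derived_to_frame(derived: Iterable[DerivedVariables]) -> pd.DataFrame:
    rows = []
    for d in derived:
        rows.append(
            {
                "trial_id": d.trial_id,
                "anticipated_enrollment": d.anticipated_enrollment,
                "actual_enrollment": d.actual_enrollment,
                "degree_of_enrollment_pct": d.degree_of_enrollment_pct,
                "trial_days": d.trial_days,
                "stop_date": "" if d.stop_date is None else d.stop_date.isoformat(),
                "start_date_used": "" if d.start_date_used is None else d.start_date_used.isoformat(),
                "summary_results": d.summary_results,
                "flags": ";".join(sorted(d.flags)),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "trial_id",
            "anticipated_enrollment",
            "actual_enrollment",
            "degree_of_enrollment_pct",
            "trial_days",
            "stop_date",
            "start_date_used",
            "summary_results",
            "flags",
        ],
    )
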