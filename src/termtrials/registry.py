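"""Domain types for versioned clinical-trial registry records and flat-file I/O.

A trial's registry entry is edited over time; each edit produces a dated
version snapshot. The analysis operates on the ordered sequence of snapshots
(:class:`TrialHistory`), not on a single download, because key variables —
the enrollment figure in force at the start, the primary completion date in
force when the status first became "terminated" — are only visible in the
history.

On disk a cohort is one long-format CSV (one row per version) plus an
optional trial-attributes CSV carrying trial-level cross-registry flags.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import pandas as pd
from pydantic import BaseModel, Field, field_validator, model_validator


class OverallStatus(str, Enum):
    completed = "completed"
    terminated = "terminated"
    recruiting = "recruiting"
    active_not_recruiting = "active_not_recruiting"
    withdrawn = "withdrawn"
    suspended = "suspended"
    unknown = "unknown"
    other = "other"


#: statuses after which a return to an active status is suspicious
TERMINAL_STATUSES = {OverallStatus.completed, OverallStatus.terminated, OverallStatus.withdrawn}

#: registry status strings → canonical status (matched case-insensitively,
#: after collapsing whitespace); anything else maps to ``other`` and is flagged
STATUS_SYNONYMS = {
    "completed": OverallStatus.completed,
    "terminated": OverallStatus.terminated,
    "recruiting": OverallStatus.recruiting,
    "enrolling by invitation": OverallStatus.recruiting,
    "not yet recruiting": OverallStatus.recruiting,
    "active, not recruiting": OverallStatus.active_not_recruiting,
    "active_not_recruiting": OverallStatus.active_not_recruiting,
    "withdrawn": OverallStatus.withdrawn,
    "suspended": OverallStatus.suspended,
    "unknown": OverallStatus.unknown,
    "unknown status": OverallStatus.unknown,
    "other": OverallStatus.other,
}


class EnrollmentType(str, Enum):
    anticipated = "anticipated"
    actual = "actual"
    #: a number was given but not marked anticipated/actual in the registry
    unmarked = "unmarked"
    #: no enrollment number in this version
    missing = "missing"


class Phase(str, Enum):
    I = "I"
    I_II = "I_II"
    II = "II"
    II_III = "II_III"
    III = "III"
    IV = "IV"
    not_given = "not_given"


WHY_STOPPED_MAX_LEN = 160


def normalize_status(raw: str) -> tuple[OverallStatus, bool]:
    """Map a registry status string to the canonical enum.

    Returns ``(status, recognized)``; unrecognized strings become
    :attr:`OverallStatus.other` with ``recognized=False``.
    """
    key = " ".join(str(raw).split()).lower()
    if key in STATUS_SYNONYMS:
        return STATUS_SYNONYMS[key], True
    return OverallStatus.other, False


def parse_registry_date(raw: str) -> tuple[Optional[dt.date], bool]:
    """Parse an ISO date, accepting month precision ("2011-06" → first of
    month, historically allowed by registries). Returns ``(date, month_only)``.
    Raises ValueError for anything else non-empty and unparseable.
    """
    s = str(raw).strip()
    if not s:
        return None, False
    try:
        return dt.date.fromisoformat(s), False
    except ValueError:
        pass
    try:
        return dt.date.fromisoformat(s + "-01"), True
    except ValueError:
        raise ValueError(f"unparseable date: {raw!r}") from None


class TrialVersion(BaseModel):
    """One snapshot of a trial's registry entry."""

    model_config = {"frozen": True}

    trial_id: str
    version_date: dt.date
    version_seq: int = Field(ge=0)
    overall_status: OverallStatus
    enrollment_count: Optional[int] = Field(default=None, ge=0)
    enrollment_type: EnrollmentType = EnrollmentType.missing
    start_date: Optional[dt.date] = None
    primary_completion_date: Optional[dt.date] = None
    why_stopped: str = ""
    has_summary_results: bool = False

    @field_validator("why_stopped")
    @classmethod
    def _why_stopped_len(cls, v: str) -> str:
        if len(v) > WHY_STOPPED_MAX_LEN:
            raise ValueError(f"why_stopped exceeds {WHY_STOPPED_MAX_LEN} characters")
        return v

    @model_validator(mode="after")
    def _enrollment_coherent(self) -> "TrialVersion":
        missing_count = self.enrollment_count is None
        missing_type = self.enrollment_type == EnrollmentType.missing
        if missing_count != missing_type:
            raise ValueError(
                "enrollment_type must be 'missing' exactly when enrollment_count is absent "
                f"(got count={self.enrollment_count!r}, type={self.enrollment_type.value!r})"
            )
        return self


class TrialHistory(BaseModel):
    """Time-ordered version snapshots of one trial, plus trial-level
    cross-registry (EUCTR-style) results flags.

    Versions are sorted on construction by ``(version_date, version_seq)``;
    duplicate keys are rejected, so the ordering is total and independent of
    input row order.
    """

    trial_id: str
    versions: tuple[TrialVersion, ...]
    euctr_results_available: bool = False
    euctr_results_tabular: bool = False

    @model_validator(mode="after")
    def _check_versions(self) -> "TrialHistory":
        if not self.versions:
            raise ValueError("TrialHistory requires at least one version")
        for v in self.versions:
            if v.trial_id != self.trial_id:
                raise ValueError(
                    f"version trial_id {v.trial_id!r} != history trial_id {self.trial_id!r}"
                )
        keys = [(v.version_date, v.version_seq) for v in self.versions]
        if len(set(keys)) != len(keys):
            dups = sorted({k for k in keys if keys.count(k) > 1})
            raise ValueError(f"duplicate (version_date, version_seq) pairs: {dups}")
        ordered = tuple(sorted(self.versions, key=lambda v: (v.version_date, v.version_seq)))
        if ordered != self.versions:
            object.__setattr__(self, "versions", ordered)
        return self

    @property
    def final_version(self) -> TrialVersion:
        return self.versions[-1]


class TrialDesign(BaseModel):
    """Design metadata needed by the SAE-eligibility cascade."""

    model_config = {"frozen": True}

    trial_id: str
    n_arms: int = Field(ge=1)
    randomized: bool
    crossover: bool = False
    active_comparator: bool = False
    any_participant_received_intervention: bool = True
    phase: Phase = Phase.not_given


class SchemaError(Exception):
    """A mandatory column is absent from an input table."""

    def __init__(self, column: str, source: str = ""):
        self.column = column
        super().__init__(f"missing mandatory column {column!r}" + (f" in {source}" if source else ""))


class DuplicateVersionError(Exception):
    """Duplicate (trial_id, version_date, version_seq) rows in an input table."""

    def __init__(self, offenders: Sequence[tuple]):
        self.offenders = list(offenders)
        super().__init__(f"duplicate version keys: {self.offenders}")


MANDATORY_COLUMNS = [
    "trial_id",
    "version_date",
    "overall_status",
    "enrollment_count",
    "enrollment_type",
    "start_date",
    "primary_completion_date",
    "why_stopped",
    "has_summary_results",
]

VERSION_COLUMNS = ["trial_id", "version_seq"] + MANDATORY_COLUMNS[1:]
ATTRIBUTE_COLUMNS = ["trial_id", "euctr_results_available", "euctr_results_tabular"]


@dataclass
class LoadResult:
    """Histories plus a machine-readable rejects report.

    ``rejects`` rows carry: row (0-based data-row index), trial_id, field,
    value, reason.  Field-level problems (e.g. a non-numeric enrollment
    count) load the row with the field missing and add a reject entry;
    row-level problems (unusable trial_id or version_date) drop the row
    into the report. ``notes`` carries file-level flags (e.g. version_seq
    assigned from file order).
    """

    histories: list[TrialHistory] = field(default_factory=list)
    rejects: list[dict] = field(default_factory=list)
    notes: list[str] = field(default_factory=list)

    def by_id(self) -> dict[str, TrialHistory]:
        return {h.trial_id: h for h in self.histories}


def _parse_bool(raw: str) -> bool:
    return str(raw).strip().lower() in {"true", "1", "yes", "t"}


def read_trial_histories(
    source: Union[str, Path],
    attributes: Optional[Union[str, Path]] = None,
) -> LoadResult:
    """Read a long-format version-history CSV into :class:`TrialHistory` objects.

    Unparseable rows/fields are collected into the rejects report, never
    silently dropped. Missing mandatory columns raise :class:`SchemaError`;
    duplicate version keys raise :class:`DuplicateVersionError`.
    """
    source = Path(source)
    df = pd.read_csv(source, dtype=str, keep_default_na=False)
    for col in MANDATORY_COLUMNS:
        if col not in df.columns:
            raise SchemaError(col, str(source))

    result = LoadResult()
    have_seq = "version_seq" in df.columns
    if not have_seq:
        result.notes.append("version_seq absent; assigned by file order within trial")

    rows_by_trial: dict[str, list[TrialVersion]] = {}
    euctr_flags: dict[str, tuple[bool, bool]] = {}
    seen_keys: set[tuple] = set()
    dup_keys: list[tuple] = []
    seq_counter: dict[str, int] = {}

    for i, row in enumerate(df.to_dict("records")):
        trial_id = str(row["trial_id"]).strip()
        if not trial_id:
            result.rejects.append(
                {"row": i, "trial_id": "", "field": "trial_id", "value": "", "reason": "empty trial_id"}
            )
            continue
        try:
            version_date, month_only = parse_registry_date(row["version_date"])
        except ValueError:
            result.rejects.append(
                {"row": i, "trial_id": trial_id, "field": "version_date",
                 "value": row["version_date"], "reason": "unparseable date"}
            )
            continue
        if version_date is None:
            result.rejects.append(
                {"row": i, "trial_id": trial_id, "field": "version_date",
                 "value": "", "reason": "missing version_date"}
            )
            continue
        if month_only:
            result.rejects.append(
                {"row": i, "trial_id": trial_id, "field": "version_date",
                 "value": row["version_date"], "reason": "month-precision date completed to first of month"}
            )

        if have_seq and str(row.get("version_seq", "")).strip():
            try:
                version_seq = int(str(row["version_seq"]).strip())
            except ValueError:
                version_seq = seq_counter.get(trial_id, 0)
                result.rejects.append(
                    {"row": i, "trial_id": trial_id, "field": "version_seq",
                     "value": row["version_seq"], "reason": "non-integer version_seq; assigned file order"}
                )
        else:
            version_seq = seq_counter.get(trial_id, 0)
        seq_counter[trial_id] = max(seq_counter.get(trial_id, 0), version_seq + 1)

        key = (trial_id, version_date, version_seq)
        if key in seen_keys:
            dup_keys.append(key)
            continue
        seen_keys.add(key)

        status, recognized = normalize_status(row["overall_status"])
        if not recognized:
            result.rejects.append(
                {"row": i, "trial_id": trial_id, "field": "overall_status",
                 "value": row["overall_status"], "reason": "unrecognized status mapped to 'other'"}
            )

        raw_count = str(row["enrollment_count"]).strip()
        raw_type = str(row["enrollment_type"]).strip().lower()
        enrollment_count: Optional[int] = None
        if raw_count:
            try:
                enrollment_count = int(raw_count)
                if enrollment_count < 0:
                    raise ValueError
            except ValueError:
                enrollment_count = None
                result.rejects.append(
                    {"row": i, "trial_id": trial_id, "field": "enrollment_count",
                     "value": raw_count, "reason": "non-integer enrollment_count dropped"}
                )
        if enrollment_count is None:
            enrollment_type = EnrollmentType.missing
        elif raw_type in ("anticipated", "estimated"):
            enrollment_type = EnrollmentType.anticipated
        elif raw_type == "actual":
            enrollment_type = EnrollmentType.actual
        else:
            enrollment_type = EnrollmentType.unmarked

        parsed_dates = {}
        for col in ("start_date", "primary_completion_date"):
            try:
                d, month_only = parse_registry_date(row[col])
            except ValueError:
                d, month_only = None, False
                result.rejects.append(
                    {"row": i, "trial_id": trial_id, "field": col,
                     "value": row[col], "reason": "unparseable date dropped"}
                )
            if month_only:
                result.rejects.append(
                    {"row": i, "trial_id": trial_id, "field": col,
                     "value": row[col], "reason": "month-precision date completed to first of month"}
                )
            parsed_dates[col] = d

        why = str(row["why_stopped"])
        if len(why) > WHY_STOPPED_MAX_LEN:
            result.rejects.append(
                {"row": i, "trial_id": trial_id, "field": "why_stopped",
                 "value": why[:40] + "...", "reason": f"truncated to {WHY_STOPPED_MAX_LEN} characters"}
            )
            why = why[:WHY_STOPPED_MAX_LEN]

        version = TrialVersion(
            trial_id=trial_id,
            version_date=version_date,
            version_seq=version_seq,
            overall_status=status,
            enrollment_count=enrollment_count,
            enrollment_type=enrollment_type,
            start_date=parsed_dates["start_date"],
            primary_completion_date=parsed_dates["primary_completion_date"],
            why_stopped=why,
            has_summary_results=_parse_bool(row["has_summary_results"]),
        )
        rows_by_trial.setdefault(trial_id, []).append(version)

    if dup_keys:
        raise DuplicateVersionError(sorted(set(dup_keys)))

    if attributes is not None:
        adf = pd.read_csv(attributes, dtype=str, keep_default_na=False)
        for col in ATTRIBUTE_COLUMNS:
            if col not in adf.columns:
                raise SchemaError(col, str(attributes))
        for row in adf.to_dict("records"):
            euctr_flags[str(row["trial_id"]).strip()] = (
                _parse_bool(row["euctr_results_available"]),
                _parse_bool(row["euctr_results_tabular"]),
            )

    for trial_id in sorted(rows_by_trial):
        avail, tabular = euctr_flags.get(trial_id, (False, False))
        result.histories.append(
            TrialHistory(
                trial_id=trial_id,
                versions=tuple(rows_by_trial[trial_id]),
                euctr_results_available=avail,
                euctr_results_tabular=tabular,
            )
        )
    return result


def write_trial_histories(
    histories: Iterable[TrialHistory],
    destination: Union[str, Path],
    attributes_destination: Optional[Union[str, Path]] = None,
) -> None:
    """Write histories as a long-format CSV (plus optional trial-attributes
    CSV). ``read_trial_histories`` on the output reproduces the input
    field-for-field: empty why_stopped stays empty, enrollment_type
    'unmarked' stays distinct from 'missing'.
    """
    rows = []
    attr_rows = []
    for h in sorted(histories, key=lambda h: h.trial_id):
        attr_rows.append(
            {
                "trial_id": h.trial_id,
                "euctr_results_available": str(h.euctr_results_available).lower(),
                "euctr_results_tabular": str(h.euctr_results_tabular).lower(),
            }
        )
        for v in h.versions:
            rows.append(
                {
                    "trial_id": v.trial_id,
                    "version_seq": v.version_seq,
                    "version_date": v.version_date.isoformat(),
                    "overall_status": v.overall_status.value,
                    "enrollment_count": "" if v.enrollment_count is None else v.enrollment_count,
                    "enrollment_type": (
                        "" if v.enrollment_type == EnrollmentType.missing else v.enrollment_type.value
                    ),
                    "start_date": "" if v.start_date is None else v.start_date.isoformat(),
                    "primary_completion_date": (
                        "" if v.primary_completion_date is None else v.primary_completion_date.isoformat()
                    ),
                    "why_stopped": v.why_stopped,
                    "has_summary_results": str(v.has_summary_results).lower(),
                }
            )
    pd.DataFrame(rows, columns=VERSION_COLUMNS).to_csv(destination, index=False, lineterminator="\n")
    if attributes_destination is not None:
        pd.DataFrame(attr_rows, columns=ATTRIBUTE_COLUMNS).to_csv(
            attributes_destination, index=False, lineterminator="\n"
        )


def write_rejects(result: LoadResult, destination: Union[str, Path]) -> None:
    pd.DataFrame(result.rejects, columns=["row", "trial_id", "field", "value", "reason"]).to_csv(
        destination, index=False, lineterminator="\n"
    )


def validate_history(history: TrialHistory) -> list[dict]:
    """Check a history for structural anomalies. Never raises; returns a
    (possibly empty) list of machine-readable issue records with keys
    ``code`` and ``detail``.

    Codes: non_monotone_dates, status_regression_after_terminal,
    negative_duration, no_actual_enrollment, missing_enrollment.
    """
    issues: list[dict] = []
    dates = [v.version_date for v in history.versions]
    if any(b < a for a, b in zip(dates, dates[1:])):
        issues.append({"code": "non_monotone_dates", "detail": "version dates decrease"})

    terminal_seen: Optional[OverallStatus] = None
    for v in history.versions:
        if terminal_seen is not None and v.overall_status in (
            OverallStatus.recruiting,
            OverallStatus.active_not_recruiting,
        ):
            issues.append(
                {
                    "code": "status_regression_after_terminal",
                    "detail": f"{v.overall_status.value} at {v.version_date} after {terminal_seen.value}",
                }
            )
            break
        if v.overall_status in TERMINAL_STATUSES:
            terminal_seen = v.overall_status

    fv = history.final_version
    if fv.start_date is not None and fv.primary_completion_date is not None:
        if fv.start_date > fv.primary_completion_date:
            issues.append(
                {
                    "code": "negative_duration",
                    "detail": f"start {fv.start_date} after primary completion {fv.primary_completion_date}",
                }
            )
    if not any(v.enrollment_type == EnrollmentType.actual for v in history.versions):
        issues.append({"code": "no_actual_enrollment", "detail": "no version with actual enrollment"})
    if not any(v.enrollment_count is not None for v in history.versions):
        issues.append({"code": "missing_enrollment", "detail": "no version carries an enrollment count"})
    return issues
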