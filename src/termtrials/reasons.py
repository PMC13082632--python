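"""Rule-based classification of the registry `why_stopped` free text.

Registries let sponsors explain a premature stop in at most 160 characters.
The taxonomy distinguishes *scientific* reasons (the accumulating evidence
itself motivated the stop: futility, external evidence, harm, unspecified
interim evidence, benefit) from *non-scientific* ones (low accrual, funding,
investigator departure, product supply, administrative/logistical/technical
issues), plus "reason not provided" and a residual "other" for vague text.

Classification is an ordered keyword/regex rule table shipped as a plain
data file (``data/reason_rules.csv``) so it can be audited and extended.
When a text mentions both a scientific and a non-scientific reason, the
scientific one is primary; among reasons of the same class, the one
mentioned first in the text wins.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd

from ._util import fmt_pct

SCIENTIFIC_CATEGORIES = (
    "evidence_of_futility",
    "external_evidence",
    "evidence_of_harm",
    "internal_evidence_unspecified",
    "evidence_of_benefit",
)
NON_SCIENTIFIC_CATEGORIES = (
    "low_accrual",
    "lack_of_funding",
    "pi_departure",
    "lack_of_investigational_product",
    "admin_logistical_technical",
)
ALL_CATEGORIES = SCIENTIFIC_CATEGORIES + NON_SCIENTIFIC_CATEGORIES + ("reason_not_provided", "other")

CATEGORY_CLASS = {
    **{c: "scientific" for c in SCIENTIFIC_CATEGORIES},
    **{c: "non_scientific" for c in NON_SCIENTIFIC_CATEGORIES},
    "reason_not_provided": "not_provided",
    "other": "other",
}

CATEGORY_DISPLAY = {
    "evidence_of_futility": "Evidence of futility",
    "external_evidence": "External evidence",
    "evidence_of_harm": "Evidence of harm",
    "internal_evidence_unspecified": "Internal evidence (unspecified)",
    "evidence_of_benefit": "Evidence of benefit",
    "low_accrual": "Low accrual rate",
    "lack_of_funding": "Lack of funding",
    "pi_departure": "Principal investigator's departure",
    "lack_of_investigational_product": "Lack of investigational product",
    "admin_logistical_technical": "Administrative, logistical or technical issues",
    "reason_not_provided": "Reason not provided",
    "other": "Other (non-specific text, unable to categorize)",
}


@dataclass(frozen=True)
class Rule:
    rule_id: str
    category: str
    pattern: re.Pattern
    priority: int


@dataclass
class ReasonAssignment:
    """Classification of one trial's termination-reason text."""

    trial_id: str
    primary_category: str
    #: every matching category with the earliest character position of its match
    all_matches: list[tuple[str, int]] = field(default_factory=list)
    rule_ids_fired: list[str] = field(default_factory=list)

    @property
    def primary_class(self) -> str:
        return CATEGORY_CLASS[self.primary_category]


@dataclass
class AgreementResult:
    """Cohen's kappa between two raters over a shared finite label set."""

    n_items: int
    observed_agreement: float
    expected_agreement: float
    kappa: Optional[float]


def load_rules(source: Optional[Union[str, Path]] = None) -> list[Rule]:
    """Load the rule table (category, pattern, priority); defaults to the
    packaged table. Rules are ordered by (priority, file order)."""
    if source is None:
        text = resources.files("termtrials.data").joinpath("reason_rules.csv").read_text("utf-8")
        lines = text.splitlines()
    else:
        lines = Path(source).read_text("utf-8").splitlines()
    rules = []
    for i, row in enumerate(csv.DictReader(lines)):
        cat = row["category"].strip()
        if cat not in CATEGORY_CLASS or cat in ("reason_not_provided", "other"):
            raise ValueError(f"rule line {i + 2}: unknown category {cat!r}")
        rules.append(
            Rule(
                rule_id=f"{cat}:{i}",
                category=cat,
                pattern=re.compile(row["pattern"].strip(), re.IGNORECASE),
                priority=int(row["priority"]),
            )
        )
    rules.sort(key=lambda r: (r.priority, r.rule_id))
    return rules


_DEFAULT_RULES: Optional[list[Rule]] = None


def _default_rules() -> list[Rule]:
    global _DEFAULT_RULES
    if _DEFAULT_RULES is None:
        _DEFAULT_RULES = load_rules()
    return _DEFAULT_RULES


def normalize_text(text: str) -> str:
    return " ".join(str(text).split()).lower()


def classify_reason(
    text: str, trial_id: str = "", rules: Optional[Sequence[Rule]] = None
) -> ReasonAssignment:
    """Classify one `why_stopped` text.

    Empty/whitespace-only text → ``reason_not_provided``; text matching no
    rule → ``other``; otherwise every matching category is recorded with the
    earliest match position and the primary is chosen by
    :func:`resolve_primary` (scientific primacy, then text order).
    The classifier is a pure function of the text: deterministic,
    case-insensitive, and invariant to whitespace normalization.
    """
    rules = _default_rules() if rules is None else rules
    norm = normalize_text(text)
    if not norm:
        return ReasonAssignment(trial_id=trial_id, primary_category="reason_not_provided")

    first_pos: dict[str, int] = {}
    fired: list[str] = []
    for rule in rules:
        m = rule.pattern.search(norm)
        if m:
            fired.append(rule.rule_id)
            pos = m.start()
            if rule.category not in first_pos or pos < first_pos[rule.category]:
                first_pos[rule.category] = pos

    matches = sorted(
        first_pos.items(), key=lambda kv: (kv[1], ALL_CATEGORIES.index(kv[0]))
    )
    primary = resolve_primary(matches)
    return ReasonAssignment(
        trial_id=trial_id, primary_category=primary, all_matches=matches, rule_ids_fired=fired
    )


def resolve_primary(matches: Sequence[tuple[str, int]]) -> str:
    """Pick the primary category from (category, position) matches: any
    scientific match beats every non-scientific one; within a class the
    earliest mention wins. No matches → ``other``."""
    if not matches:
        return "other"
    sci = [m for m in matches if CATEGORY_CLASS[m[0]] == "scientific"]
    pool = sci if sci else [m for m in matches if CATEGORY_CLASS[m[0]] == "non_scientific"]
    if not pool:
        return "other"
    return min(pool, key=lambda kv: (kv[1], ALL_CATEGORIES.index(kv[0])))[0]


def cohens_kappa(labels_a: Sequence, labels_b: Sequence) -> AgreementResult:
    """Chance-corrected inter-rater agreement.

    observed = fraction of identical labels; expected = Σ_c p_a(c)·p_b(c);
    kappa = (observed − expected) / (1 − expected). Perfect agreement is
    kappa 1 even at the expected=1 boundary; expected=1 with imperfect
    agreement is undefined and reported as ``None``.
    """
    if len(labels_a) != len(labels_b):
        raise ValueError(f"label sequences differ in length ({len(labels_a)} vs {len(labels_b)})")
    n = len(labels_a)
    if n == 0:
        raise ValueError("kappa requires at least one item")
    observed = sum(a == b for a, b in zip(labels_a, labels_b)) / n
    cats = set(labels_a) | set(labels_b)
    pa = {c: sum(x == c for x in labels_a) / n for c in cats}
    pb = {c: sum(x == c for x in labels_b) / n for c in cats}
    expected = sum(pa[c] * pb[c] for c in cats)
    if observed == 1.0:
        kappa: Optional[float] = 1.0
    elif expected >= 1.0:
        kappa = None
    else:
        kappa = (observed - expected) / (1 - expected)
    return AgreementResult(n_items=n, observed_agreement=observed, expected_agreement=expected, kappa=kappa)


ROW_ORDER = (
    list(SCIENTIFIC_CATEGORIES)
    + ["total_scientific"]
    + list(NON_SCIENTIFIC_CATEGORIES)
    + ["total_non_scientific", "reason_not_provided", "other", "total"]
)


def tabulate_reasons(
    assignments: Sequence[ReasonAssignment],
    cohort_labels: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Build the reason-count table: per-category counts and within-cohort
    percentages, class subtotals, and a grand total.

    Percentages use the cohort's terminated-trial count as denominator,
    integer-rounded except one decimal below 1%. With multiple cohorts a
    pooled "Total" column is appended.
    """
    if cohort_labels is None:
        cohort_labels = ["cohort"] * len(assignments)
    if len(cohort_labels) != len(assignments):
        raise ValueError("cohort_labels must parallel assignments")

    cohorts = list(dict.fromkeys(cohort_labels)) or ["cohort"]
    if len(cohorts) > 1:
        cohorts.append("Total")

    counts = {c: {cat: 0 for cat in ALL_CATEGORIES} for c in cohorts}
    for a, label in zip(assignments, cohort_labels):
        counts[label][a.primary_category] += 1
    if "Total" in counts:
        for a in assignments:
            counts["Total"][a.primary_category] += 1

    data: dict[str, list] = {}
    for cohort in cohorts:
        c = counts[cohort]
        n = sum(c.values())
        col_n, col_pct = [], []
        for row in ROW_ORDER:
            if row == "total_scientific":
                k = sum(c[cat] for cat in SCIENTIFIC_CATEGORIES)
            elif row == "total_non_scientific":
                k = sum(c[cat] for cat in NON_SCIENTIFIC_CATEGORIES)
            elif row == "total":
                k = n
            else:
                k = c[row]
            col_n.append(k)
            col_pct.append(fmt_pct(k, n))
        data[f"{cohort}_n"] = col_n
        data[f"{cohort}_pct"] = col_pct
    return pd.DataFrame(data, index=ROW_ORDER)


def assignments_to_frame(assignments: Sequence[ReasonAssignment]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "trial_id": [a.trial_id for a in assignments],
            "primary_category": [a.primary_category for a in assignments],
            "primary_class": [a.primary_class for a in assignments],
            "all_matches": [
                ";".join(f"{cat}@{pos}" for cat, pos in a.all_matches) for a in assignments
            ],
            "rule_ids_fired": [";".join(a.rule_ids_fired) for a in assignments],
        }
    )
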