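"""Map trial MeSH condition terms to high-level therapeutic-focus categories.

MeSH tree numbers (e.g. ``C04.588.180``) encode a term's position in the
NLM hierarchy; the first dot-segment (``C04``) identifies the top-of-branch
heading ("Neoplasms"). A trial's therapeutic foci are the deduplicated set
of top-level headings reached from its submitted condition terms — so
"breast cyst", sitting under a C04-rooted number, contributes "Neoplasms".
A trial can have no focus (nothing submitted), one, or several; cohort
tabulation counts focus *occurrences*, allowing multiple foci per trial.

The tree is a local term → tree-number table (no network lookup).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import pandas as pd

TREE_NUMBER_RE = re.compile(r"^[A-Z]\d{2}(\.[A-Za-z0-9]+)*$")

UNLABELED_BUCKET = "Unlabeled"


class MeshLoadError(Exception):
    pass


@dataclass
class MeshTree:
    """Term → tree-number mapping with display labels for top-level codes.

    Term lookup is case-insensitive; a term may carry tree numbers under
    several top-level codes. Codes without a display label fall into the
    declared "Unlabeled" bucket rather than failing.
    """

    entries: dict[str, frozenset[str]]
    category_labels: dict[str, str]

    def lookup(self, term: str) -> frozenset[str]:
        return self.entries.get(" ".join(str(term).split()).lower(), frozenset())

    def label_for(self, top_code: str) -> str:
        return self.category_labels.get(top_code, UNLABELED_BUCKET)

    def save(self, term_destination: Union[str, Path], labels_destination: Union[str, Path]) -> None:
        rows = [
            {"term": term, "tree_number": num}
            for term in sorted(self.entries)
            for num in sorted(self.entries[term])
        ]
        pd.DataFrame(rows, columns=["term", "tree_number"]).to_csv(
            term_destination, index=False, lineterminator="\n"
        )
        lab = [{"code": c, "label": self.category_labels[c]} for c in sorted(self.category_labels)]
        pd.DataFrame(lab, columns=["code", "label"]).to_csv(
            labels_destination, index=False, lineterminator="\n"
        )


@dataclass
class TrialFoci:
    """Therapeutic foci of one trial: a deduplicated set of top-level
    headings, or unassigned (no terms submitted / none resolvable)."""

    trial_id: str
    foci: frozenset[str] = frozenset()
    unassigned: bool = False
    #: "no_terms" | "unresolvable" | None
    unassigned_reason: Optional[str] = None


def load_mesh_tree(
    term_source: Union[str, Path], labels_source: Union[str, Path]
) -> MeshTree:
    """Load term→tree-number and code→label CSVs. Duplicate term rows merge
    their tree-number sets; a malformed tree number raises
    :class:`MeshLoadError` naming the line."""
    tdf = pd.read_csv(term_source, dtype=str, keep_default_na=False)
    for col in ("term", "tree_number"):
        if col not in tdf.columns:
            raise MeshLoadError(f"missing column {col!r} in {term_source}")
    entries: dict[str, set[str]] = {}
    for i, row in enumerate(tdf.to_dict("records")):
        num = row["tree_number"].strip()
        if not TREE_NUMBER_RE.match(num):
            raise MeshLoadError(f"{term_source}, line {i + 2}: malformed tree number {num!r}")
        key = " ".join(row["term"].split()).lower()
        entries.setdefault(key, set()).add(num)

    ldf = pd.read_csv(labels_source, dtype=str, keep_default_na=False)
    for col in ("code", "label"):
        if col not in ldf.columns:
            raise MeshLoadError(f"missing column {col!r} in {labels_source}")
    labels = {row["code"].strip(): row["label"].strip() for row in ldf.to_dict("records")}
    return MeshTree(
        entries={k: frozenset(v) for k, v in entries.items()},
        category_labels=labels,
    )


def top_code(tree_number: str) -> str:
    return tree_number.split(".", 1)[0]


def map_term_to_foci(term: str, tree: MeshTree) -> frozenset[str]:
    """Resolve one condition term to its top-level display names: each tree
    number is truncated to its first dot-segment and mapped through the
    label table. Unknown terms map to the empty set."""
    return frozenset(tree.label_for(top_code(num)) for num in tree.lookup(term))


def assign_trial_foci(
    trial_id: str, condition_terms: Sequence[str], tree: MeshTree
) -> TrialFoci:
    """Union the per-term mappings into the trial's focus set (deduplicated;
    independent of term order and duplication). Trials with no submitted
    terms and trials whose terms all fail to resolve are both unassigned,
    flagged distinctly."""
    if not condition_terms:
        return TrialFoci(trial_id=trial_id, unassigned=True, unassigned_reason="no_terms")
    foci: set[str] = set()
    for term in condition_terms:
        foci |= map_term_to_foci(term, tree)
    if not foci:
        return TrialFoci(trial_id=trial_id, unassigned=True, unassigned_reason="unresolvable")
    return TrialFoci(trial_id=trial_id, foci=frozenset(foci))


def tabulate_foci(
    trial_foci: Iterable[TrialFoci],
    collapse_keep: Optional[Sequence[str]] = None,
    include_unassigned: bool = True,
) -> pd.DataFrame:
    """Tabulate focus occurrences across trials, allowing multiple foci per
    study. Percentages are of total occurrences (Σ per-trial focus-set sizes
    plus, by default, one occurrence per unassigned trial), not of unique
    trials. ``collapse_keep`` folds every category outside the given list
    into "Miscellaneous"."""
    occurrences: dict[str, int] = {}
    n_unassigned = 0
    for tf in trial_foci:
        if tf.unassigned:
            n_unassigned += 1
            continue
        for label in tf.foci:
            if collapse_keep is not None and label not in collapse_keep:
                label = "Miscellaneous"
            occurrences[label] = occurrences.get(label, 0) + 1

    rows = []
    if collapse_keep is not None:
        order = [c for c in collapse_keep if c in occurrences]
        if "Miscellaneous" in occurrences:
            order.append("Miscellaneous")
    else:
        order = sorted(occurrences, key=lambda c: (-occurrences[c], c))
    denom = sum(occurrences.values()) + (n_unassigned if include_unassigned else 0)
    for label in order:
        rows.append({"category": label, "occurrences": occurrences[label]})
    if include_unassigned:
        rows.append({"category": "No assigned foci", "occurrences": n_unassigned})
    df = pd.DataFrame(rows, columns=["category", "occurrences"])
    df["pct"] = 100.0 * df["occurrences"] / denom if denom else 0.0
    return df
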