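"""Cohort-characteristics reporting and the end-to-end pipeline.

Assembles the per-cohort characteristics table (phase distribution, results
reporting by route, enrollment medians/IQRs and aggregate degree of
enrollment, days until termination, therapeutic foci) and the termination
reason table, comparing terminated against completed trials within one
cohort; trials with any other recruitment status are excluded and counted.

``run_pipeline`` chains the stages (load/generate → validate → derive →
classify → foci → cascade → meta → report), writing every intermediate
artifact plus a run log, deterministically for a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from . import __version__
from ._util import fmt_pct
from .derivation import (
    FLAG_EXCLUDED_UNCLEAR,
    DerivedVariables,
    aggregate_degree_of_enrollment,
    derive_variables,
    derived_to_frame,
)
from .mesh import TrialFoci, assign_trial_foci, tabulate_foci
from .meta import (
    CascadeRecord,
    build_two_by_two,
    effects_to_frame,
    eligibility_cascade,
    forest_data,
    pool_common_effect,
    pool_random_effects,
    pooled_to_dict,
    study_effect,
)
from .reasons import ReasonAssignment, assignments_to_frame, classify_reason, tabulate_reasons
from .registry import (
    OverallStatus,
    Phase,
    TrialHistory,
    read_trial_histories,
    validate_history,
    write_rejects,
)
from .synthetic import (
    CohortConfig,
    generate_cohort,
    generate_mesh_fixture,
    read_arm_annotations,
    read_conditions,
    read_designs,
    read_publications,
    read_sae_tables,
    write_cohort,
)

#: registry phase strings → canonical phase (case/whitespace-insensitive)
PHASE_SYNONYMS = {
    "phase 1": Phase.I,
    "early phase 1": Phase.I,
    "phase 1/phase 2": Phase.I_II,
    "phase 2": Phase.II,
    "phase 2/phase 3": Phase.II_III,
    "phase 3": Phase.III,
    "phase 4": Phase.IV,
    "i": Phase.I,
    "i_ii": Phase.I_II,
    "ii": Phase.II,
    "ii_iii": Phase.II_III,
    "iii": Phase.III,
    "iv": Phase.IV,
    "": Phase.not_given,
    "n/a": Phase.not_given,
    "not applicable": Phase.not_given,
    "not given": Phase.not_given,
    "not_given": Phase.not_given,
}


def normalize_phase(raw: str) -> Phase:
    return PHASE_SYNONYMS.get(" ".join(str(raw).split()).lower(), Phase.not_given)


class JoinError(Exception):
    def __init__(self, trial_ids: Sequence[str]):
        self.trial_ids = sorted(trial_ids)
        super().__init__(f"trials present in derived data but absent from histories: {self.trial_ids}")


@dataclass
class CohortReport:
    cohort_label: str
    status_counts: dict[str, int]
    phase_table: pd.DataFrame
    results_table: pd.DataFrame
    enrollment_summary: dict
    trial_days_summary: dict
    foci_table: pd.DataFrame
    reasons_table: pd.DataFrame


def _median_iqr(values: Sequence[float]) -> Optional[dict]:
    """Median and 25th–75th percentile via linear interpolation."""
    vals = [v for v in values if v is not None]
    if not vals:
        return None
    arr = np.asarray(vals, dtype=float)
    return {
        "n": len(vals),
        "median": float(np.percentile(arr, 50)),
        "q25": float(np.percentile(arr, 25)),
        "q75": float(np.percentile(arr, 75)),
    }


def build_cohort_report(
    histories: Sequence[TrialHistory],
    derived: Mapping[str, DerivedVariables],
    assignments: Mapping[str, ReasonAssignment],
    foci: Mapping[str, TrialFoci],
    publication_flags: Mapping[str, bool],
    designs: Optional[Mapping[str, object]] = None,
    cohort_label: str = "cohort",
) -> CohortReport:
    """Assemble the within-cohort characteristics report.

    Only terminated and completed trials (by final-version status) enter
    the tabulations; other statuses are counted under ``other_excluded``.
    Publication flags are an external input (publication search is out of
    scope). Every percentage in the report is recomputable from the counts
    printed beside it; :func:`check_report` asserts this.
    """
    by_id = {h.trial_id: h for h in histories}
    missing = [t for t in derived if t not in by_id]
    if missing:
        raise JoinError(missing)

    groups: dict[str, list[str]] = {"terminated": [], "completed": []}
    n_other = 0
    for h in histories:
        status = h.final_version.overall_status
        if status == OverallStatus.terminated:
            groups["terminated"].append(h.trial_id)
        elif status == OverallStatus.completed:
            groups["completed"].append(h.trial_id)
        else:
            n_other += 1
    status_counts = {
        "terminated": len(groups["terminated"]),
        "completed": len(groups["completed"]),
        "other_excluded": n_other,
    }

    # phase distribution (needs design metadata; absent → all not_given)
    phase_rows = []
    for phase in Phase:
        row = {"phase": phase.value}
        for g, ids in groups.items():
            k = sum(
                1
                for t in ids
                if (designs or {}).get(t) is not None
                and getattr(designs[t], "phase", Phase.not_given) == phase
            )
            if designs is None:
                k = len(ids) if phase == Phase.not_given else 0
            row[f"{g}_n"] = k
            row[f"{g}_pct"] = fmt_pct(k, len(ids))
        phase_rows.append(row)
    phase_table = pd.DataFrame(phase_rows)

    # results reporting by route
    res_rows = []
    for route in ("summary_results", "publication", "any"):
        row = {"route": route}
        for g, ids in groups.items():
            if route == "summary_results":
                k = sum(1 for t in ids if derived[t].summary_results != "none")
            elif route == "publication":
                k = sum(1 for t in ids if publication_flags.get(t, False))
            else:
                k = sum(
                    1
                    for t in ids
                    if derived[t].summary_results != "none" or publication_flags.get(t, False)
                )
            row[f"{g}_n"] = k
            row[f"{g}_pct"] = fmt_pct(k, len(ids))
        res_rows.append(row)
    results_table = pd.DataFrame(res_rows)

    enrollment_summary: dict = {}
    for g, ids in groups.items():
        dvs = [derived[t] for t in ids if t in derived]
        agg = aggregate_degree_of_enrollment(dvs) if dvs else None
        enrollment_summary[g] = {
            "anticipated": _median_iqr([d.anticipated_enrollment for d in dvs]),
            "actual": _median_iqr([d.actual_enrollment for d in dvs]),
            "aggregate_degree_pct": None if agg is None else agg.pct,
            "aggregate_degree_pct_rounded": None if agg is None else agg.pct_rounded,
            "n_usable": 0 if agg is None else agg.n_usable,
            "n_excluded_unclear": sum(1 for d in dvs if FLAG_EXCLUDED_UNCLEAR in d.flags),
        }

    trial_days_summary = {
        "terminated": _median_iqr(
            [derived[t].trial_days for t in groups["terminated"] if t in derived]
        )
    }

    foci_table = tabulate_foci(
        [foci[t] for g in ("terminated", "completed") for t in groups[g] if t in foci]
    )

    term_assignments = [assignments[t] for t in groups["terminated"] if t in assignments]
    reasons_table = tabulate_reasons(term_assignments, [cohort_label] * len(term_assignments))

    report = CohortReport(
        cohort_label=cohort_label,
        status_counts=status_counts,
        phase_table=phase_table,
        results_table=results_table,
        enrollment_summary=enrollment_summary,
        trial_days_summary=trial_days_summary,
        foci_table=foci_table,
        reasons_table=reasons_table,
    )
    check_report(report)
    return report


def check_report(report: CohortReport) -> None:
    """Self-consistency: every percentage recomputes from the counts in the
    same table, and the any-results count is at least each single route."""
    n_by_group = {
        "terminated": report.status_counts["terminated"],
        "completed": report.status_counts["completed"],
    }
    for table in (report.phase_table, report.results_table):
        for g, n in n_by_group.items():
            for _, row in table.iterrows():
                assert row[f"{g}_pct"] == fmt_pct(row[f"{g}_n"], n), (
                    f"inconsistent percentage in report: {row.to_dict()}"
                )
    res = report.results_table.set_index("route")
    for g in n_by_group:
        assert res.loc["any", f"{g}_n"] >= res.loc["summary_results", f"{g}_n"]
        assert res.loc["any", f"{g}_n"] >= res.loc["publication", f"{g}_n"]


def report_to_dict(report: CohortReport) -> dict:
    return {
        "cohort_label": report.cohort_label,
        "status_counts": report.status_counts,
        "phase_table": report.phase_table.to_dict("records"),
        "results_table": report.results_table.to_dict("records"),
        "enrollment_summary": report.enrollment_summary,
        "trial_days_summary": report.trial_days_summary,
        "foci_table": report.foci_table.to_dict("records"),
        "reasons_table": report.reasons_table.reset_index(names="row").to_dict("records"),
    }


# ---------------------------------------------------------------------------
# pipeline


class ConfigError(Exception):
    pass


def _load_config(config: Union[str, Path, dict]) -> dict:
    if isinstance(config, dict):
        return config
    path = Path(config)
    text = path.read_text("utf-8")
    if path.suffix in (".yaml", ".yml"):
        return yaml.safe_load(text)
    return json.loads(text)


def run_pipeline(config: Union[str, Path, dict], out_dir: Optional[Union[str, Path]] = None) -> Path:
    """Execute the full pipeline from a YAML/JSON config.

    The config either requests synthetic generation (``synthetic:`` mapping
    of :class:`~termtrials.synthetic.CohortConfig` fields) or names input
    files (``inputs:`` with versions/attributes/designs/conditions/sae/
    annotations/publications paths). Every stage writes its artifact into
    the output directory; a run log records the seed and per-stage counts.
    Outputs are byte-identical across reruns with the same config.
    """
    cfg = _load_config(config)
    out = Path(out_dir if out_dir is not None else cfg.get("out", "pipeline_out"))
    out.mkdir(parents=True, exist_ok=True)
    log: dict = {"package_version": __version__, "stages": {}}

    mesh_tree = generate_mesh_fixture()

    if "synthetic" in cfg:
        cohort_cfg = CohortConfig(**cfg["synthetic"])
        log["seed"] = cohort_cfg.seed
        cohort = generate_cohort(cohort_cfg)
        write_cohort(cohort, out / "cohort")
        histories = cohort.histories
        designs = {d.trial_id: d for d in cohort.designs}
        conditions = cohort.conditions
        sae_tables = cohort.sae_tables
        annotations = cohort.arm_annotations
        publications = cohort.publications
    elif "inputs" in cfg:
        inp = cfg["inputs"]
        for key in ("versions",):
            if key not in inp:
                raise ConfigError(f"config inputs missing required path {key!r}")
        loaded = read_trial_histories(inp["versions"], inp.get("attributes"))
        write_rejects(loaded, out / "rejects.csv")
        histories = loaded.histories
        designs = {d.trial_id: d for d in read_designs(inp["designs"])} if "designs" in inp else {}
        conditions = read_conditions(inp["conditions"]) if "conditions" in inp else {}
        sae_tables = read_sae_tables(inp["sae"]) if "sae" in inp else {}
        annotations = read_arm_annotations(inp["annotations"]) if "annotations" in inp else []
        publications = read_publications(inp["publications"]) if "publications" in inp else {}
    else:
        raise ConfigError("config must contain either 'synthetic' or 'inputs'")
    log["stages"]["load"] = {"n_trials": len(histories)}

    # validate
    issues = []
    for h in histories:
        for issue in validate_history(h):
            issues.append({"trial_id": h.trial_id, **issue})
    pd.DataFrame(issues, columns=["trial_id", "code", "detail"]).to_csv(
        out / "validation_issues.csv", index=False, lineterminator="\n"
    )
    log["stages"]["validate"] = {"n_issues": len(issues)}

    # derive
    derived = {h.trial_id: derive_variables(h) for h in histories}
    derived_to_frame(derived.values()).to_csv(out / "derived.csv", index=False, lineterminator="\n")
    log["stages"]["derive"] = {"n_trials": len(derived)}

    # classify (terminated trials only carry reason text)
    assignments = {}
    for h in histories:
        if h.final_version.overall_status == OverallStatus.terminated:
            assignments[h.trial_id] = classify_reason(h.final_version.why_stopped, h.trial_id)
    assignments_to_frame(list(assignments.values())).to_csv(
        out / "reason_assignments.csv", index=False, lineterminator="\n"
    )
    log["stages"]["classify"] = {"n_terminated": len(assignments)}

    # foci
    foci = {
        h.trial_id: assign_trial_foci(h.trial_id, conditions.get(h.trial_id, []), mesh_tree)
        for h in histories
    }
    pd.DataFrame(
        [
            {
                "trial_id": tf.trial_id,
                "foci": ";".join(sorted(tf.foci)),
                "unassigned": str(tf.unassigned).lower(),
                "unassigned_reason": tf.unassigned_reason or "",
            }
            for tf in (foci[h.trial_id] for h in histories)
        ]
    ).to_csv(out / "trial_foci.csv", index=False, lineterminator="\n")
    log["stages"]["foci"] = {"n_trials": len(foci)}

    # SAE eligibility cascade
    by_id = {h.trial_id: h for h in histories}
    records = [
        CascadeRecord(
            trial_id=t,
            reason_class=assignments[t].primary_class,
            summary_results=derived[t].summary_results,
            euctr_results_tabular=by_id[t].euctr_results_tabular,
            design=designs.get(t),
        )
        for t in sorted(assignments)
    ]
    elig = eligibility_cascade(records)
    (out / "cascade.json").write_text(
        json.dumps(
            {
                "n_candidates": elig.n_candidates,
                "n_with_tabular_results": elig.n_with_tabular_results,
                "exclusions": elig.exclusions,
                "included_trial_ids": elig.included_trial_ids,
            },
            indent=2,
            sort_keys=True,
        ),
        "utf-8",
    )
    log["stages"]["cascade"] = {
        "n_candidates": elig.n_candidates,
        "n_included": len(elig.included_trial_ids),
    }

    # meta-analysis over included trials with usable arm data
    effects = []
    for t in elig.included_trial_ids:
        if t in sae_tables:
            arms = sae_tables[t]
            anns = [a for a in annotations if a.trial_id == t]
            effects.append(study_effect(build_two_by_two(arms, anns)))
    meta_out: dict = {"k_supplied": len(effects)}
    estimable = [e for e in effects if not e.excluded_zero_both]
    if estimable:
        common = pool_common_effect(effects)
        random_ = pool_random_effects(effects)
        meta_out["common_effect"] = pooled_to_dict(common)
        meta_out["random_effects"] = pooled_to_dict(random_)
        effects_to_frame(effects).to_csv(out / "study_effects.csv", index=False, lineterminator="\n")
        forest_data(effects, common, random_).to_csv(
            out / "forest.csv", index=False, lineterminator="\n"
        )
    (out / "meta.json").write_text(json.dumps(meta_out, indent=2, sort_keys=True), "utf-8")
    log["stages"]["meta"] = {"k": len(estimable)}

    # cohort report
    report = build_cohort_report(
        histories,
        derived,
        assignments,
        foci,
        publications,
        designs=designs,
        cohort_label=cfg.get("cohort_label", "cohort"),
    )
    (out / "report.json").write_text(
        json.dumps(report_to_dict(report), indent=2, sort_keys=True), "utf-8"
    )
    log["stages"]["report"] = {"terminated": report.status_counts["terminated"]}

    (out / "run_log.json").write_text(json.dumps(log, indent=2, sort_keys=True), "utf-8")
    return out
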