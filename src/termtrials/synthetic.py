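"""Seeded synthetic registry cohorts for end-to-end, download-free testing.

The generator emits everything the downstream stages consume — version
histories, trial designs, MeSH condition terms, arm-level SAE tables,
arm-role annotations, publication flags — together with a ``truth`` record
of the generating parameters, so every stage can be validated against known
ground truth.

Defaults emulate the cohort statistics the analysis targets: ~10% of trials
terminated; termination reasons drawn from the observed pooled taxonomy mix
(low accrual dominating the non-scientific class); anticipated enrollment
log-normal with median ~80; terminated trials attaining ~39% of plan in
aggregate, with a small fraction over-enrolling past 100%; durations around
1,000 days; summary-results probability 0.29 for terminated vs 0.10 for
completed trials. SAE tables are generated from a configurable true
intervention-vs-control log risk ratio with between-trial heterogeneity.

Reason texts are template-sampled (not free-form) so classifier tests have
exact ground truth; templates include paraphrases ("slow accrual",
"insufficient recruitment") and dual-reason texts joining a scientific and
a non-scientific clause. Randomness is a single seed split hierarchically
per trial, so adding trials never perturbs earlier ones.
"""

from __future__ import annotations

import datetime as dt
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Union

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator

from ._util import sample_law
from .mesh import MeshTree
from .meta import ArmAnnotation, ArmRole, ArmSAETable
from .registry import (
    EnrollmentType,
    OverallStatus,
    Phase,
    TrialDesign,
    TrialHistory,
    TrialVersion,
    write_trial_histories,
)

# ---------------------------------------------------------------------------
# reason-text templates (co-designed with the classifier rule table; the
# classifier must recover the truth category for every template)

REASON_TEMPLATES: dict[str, list[str]] = {
    "evidence_of_futility": [
        "Terminated for futility",
        "Stopped early due to futility at the planned interim analysis",
        "Lack of efficacy observed",
        "Study unlikely to meet the primary endpoint",
    ],
    "external_evidence": [
        "Terminated based on external evidence",
        "Stopped after results from another trial became available",
        "Newly published data answered the study question",
    ],
    "evidence_of_harm": [
        "Terminated due to safety concerns",
        "Unacceptable toxicity observed in the treatment arm",
        "High rate of serious adverse reactions",
    ],
    "internal_evidence_unspecified": [
        "Terminated following interim analysis",
        "Stopped after review of interim data",
        "Terminated on DSMB recommendation",
    ],
    "evidence_of_benefit": [
        "Stopped early due to evidence of benefit",
        "Trial met its primary endpoint early",
        "Stopped for overwhelming efficacy",
    ],
    "low_accrual": [
        "Terminated due to slow accrual",
        "Insufficient recruitment",
        "Poor enrollment of participants",
        "Unable to recruit sufficient patients",
        "Low accrual rate",
    ],
    "lack_of_funding": [
        "Lack of funding",
        "Study terminated due to financial constraints",
        "Sponsor budget cuts",
        "Grant not renewed",
    ],
    "pi_departure": [
        "Principal investigator left the institution",
        "Departure of the principal investigator",
        "The PI left the site",
    ],
    "lack_of_investigational_product": [
        "Study drug supply interrupted",
        "Investigational product no longer available",
        "Drug supply issues",
        "Product was withdrawn from the market",
    ],
    "admin_logistical_technical": [
        "Terminated for administrative reasons",
        "Sponsor decision to close the study",
        "Logistical issues at participating sites",
        "Study closed for strategic reasons",
        "Technical problems with the study device",
    ],
}

#: vague texts the taxonomy cannot place (ground truth: "other")
VAGUE_TEMPLATES = [
    "Protocol modification",
    "Core study 12011.201 was terminated",
    "See detailed description",
    "Study halted",
]

#: (text, truth category) for texts naming both a scientific and a
#: non-scientific reason — the scientific one is primary
DUAL_REASON_TEMPLATES: list[tuple[str, str]] = [
    ("Stopped for futility after interim analysis; recruitment was also slow", "evidence_of_futility"),
    ("Terminated due to safety concerns; enrollment was also below target", "evidence_of_harm"),
    ("Slow accrual; evidence of futility at interim analysis", "evidence_of_futility"),
    ("Funding withdrawn; unacceptable toxicity emerged", "evidence_of_harm"),
]

#: pooled taxonomy mix observed across 367 terminated trials
DEFAULT_REASON_MIX = {
    "evidence_of_futility": 32 / 367,
    "external_evidence": 23 / 367,
    "evidence_of_harm": 15 / 367,
    "internal_evidence_unspecified": 5 / 367,
    "evidence_of_benefit": 4 / 367,
    "low_accrual": 177 / 367,
    "lack_of_funding": 15 / 367,
    "pi_departure": 3 / 367,
    "lack_of_investigational_product": 12 / 367,
    "admin_logistical_technical": 34 / 367,
    "reason_not_provided": 37 / 367,
    "vague": 10 / 367,
}

PHASES = [Phase.I, Phase.I_II, Phase.II, Phase.II_III, Phase.III, Phase.IV, Phase.not_given]
PHASE_PROBS = [0.06, 0.04, 0.27, 0.05, 0.20, 0.13, 0.25]


class SAEConfig(BaseModel):
    """Generating law for arm-level SAE counts: control-arm risk from
    ``baseline_sae_risk_law``, intervention risk scaled by
    ``exp(true_log_rr + tau·N(0,1))`` per trial."""

    true_log_rr: float = 0.0
    tau: float = Field(default=0.2, ge=0)
    baseline_sae_risk_law: dict = Field(default_factory=lambda: {"kind": "beta", "a": 2.0, "b": 8.0})
    arm_size_law: dict = Field(
        default_factory=lambda: {"kind": "lognormal", "mu": math.log(50.0), "sigma": 0.5}
    )


class CohortConfig(BaseModel):
    """Full parameterization of a synthetic cohort."""

    seed: int = 0
    n_trials: int = Field(default=200, gt=0)
    terminated_fraction: float = Field(default=0.10, ge=0, le=1)
    other_status_fraction: float = Field(default=0.05, ge=0, le=1)
    reason_mix: dict[str, float] = Field(default_factory=lambda: dict(DEFAULT_REASON_MIX))
    dual_reason_prob: float = Field(default=9 / 367, ge=0, le=1)
    anticipated_enrollment_law: dict = Field(
        default_factory=lambda: {"kind": "lognormal", "mu": math.log(80.0), "sigma": 1.0}
    )
    enrollment_attainment_law_terminated: dict = Field(
        default_factory=lambda: {"kind": "gamma", "shape": 2.0, "scale": 0.195}
    )
    enrollment_attainment_law_completed: dict = Field(
        default_factory=lambda: {"kind": "gamma", "shape": 12.0, "scale": 0.08}
    )
    duration_law: dict = Field(
        default_factory=lambda: {"kind": "lognormal", "mu": math.log(1000.0), "sigma": 0.6}
    )
    summary_results_prob: dict[str, float] = Field(
        default_factory=lambda: {"terminated": 0.29, "completed": 0.10}
    )
    publication_prob: dict[str, float] = Field(
        default_factory=lambda: {"terminated": 0.32, "completed": 0.77}
    )
    euctr_results_prob: float = Field(default=0.15, ge=0, le=1)
    euctr_tabular_prob: float = Field(default=0.7, ge=0, le=1)
    # corruption knobs (off by default)
    missing_actual_prob: float = Field(default=0.0, ge=0, le=1)
    unmarked_enrollment_prob: float = Field(default=0.0, ge=0, le=1)
    missing_why_stopped_prob: float = Field(default=0.0, ge=0, le=1)
    sae: SAEConfig = Field(default_factory=SAEConfig)

    @field_validator("reason_mix")
    @classmethod
    def _mix_valid(cls, v: dict[str, float]) -> dict[str, float]:
        allowed = set(REASON_TEMPLATES) | {"reason_not_provided", "vague"}
        unknown = set(v) - allowed
        if unknown:
            raise ValueError(f"unknown reason_mix keys: {sorted(unknown)}")
        if any(p < 0 for p in v.values()):
            raise ValueError("reason_mix probabilities must be non-negative")
        if abs(sum(v.values()) - 1.0) > 1e-9:
            raise ValueError(f"reason_mix must sum to 1 (got {sum(v.values())!r})")
        return v


@dataclass
class SyntheticCohort:
    histories: list[TrialHistory]
    designs: list[TrialDesign]
    conditions: dict[str, list[str]]
    sae_tables: dict[str, list[ArmSAETable]]
    arm_annotations: list[ArmAnnotation]
    publications: dict[str, bool]
    truth: dict[str, Any]


def _int_date(base: dt.date, offset_days: int) -> dt.date:
    return base + dt.timedelta(days=int(offset_days))


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Generate a cohort deterministically from ``config.seed``.

    Every terminated trial's history contains a version in which the status
    first becomes terminated, carrying both start and primary completion
    dates; anticipated enrollment appears in the first version (dated at the
    start date) with type ``anticipated``; reason texts come from the
    category templates and the per-trial truth category is recorded.
    """
    root = np.random.SeedSequence(config.seed)
    children = root.spawn(config.n_trials)
    mesh_terms = sorted(generate_mesh_fixture().entries)
    mix_keys = sorted(config.reason_mix)
    mix_probs = np.array([config.reason_mix[k] for k in mix_keys])
    mix_probs = mix_probs / mix_probs.sum()
    base_date = dt.date(2010, 1, 1)

    histories: list[TrialHistory] = []
    designs: list[TrialDesign] = []
    conditions: dict[str, list[str]] = {}
    sae_tables: dict[str, list[ArmSAETable]] = {}
    annotations: list[ArmAnnotation] = []
    publications: dict[str, bool] = {}
    truth: dict[str, Any] = {
        "config": config.model_dump(mode="json"),
        "trials": {},
    }

    for i in range(config.n_trials):
        rng = np.random.default_rng(children[i])
        trial_id = f"NCT{90000000 + i:08d}"

        u = rng.random()
        if u < config.terminated_fraction:
            group = "terminated"
        elif u < config.terminated_fraction + config.other_status_fraction:
            group = "other"
        else:
            group = "completed"

        start = _int_date(base_date, rng.integers(0, 2557))
        anticipated = max(2, int(round(sample_law(rng, config.anticipated_enrollment_law, 1)[0])))
        planned_duration = max(30, int(round(sample_law(rng, config.duration_law, 1)[0])))

        if group == "terminated":
            duration = max(30, int(round(sample_law(rng, config.duration_law, 1)[0] * 0.8)))
            attainment = float(sample_law(rng, config.enrollment_attainment_law_terminated, 1)[0])
        else:
            duration = planned_duration
            attainment = float(sample_law(rng, config.enrollment_attainment_law_completed, 1)[0])
        actual = max(0, int(round(anticipated * attainment)))
        stop = _int_date(start, duration)

        # termination reason
        reason_category = None
        reason_text = ""
        if group == "terminated":
            if rng.random() < config.dual_reason_prob:
                idx = int(rng.integers(len(DUAL_REASON_TEMPLATES)))
                reason_text, reason_category = DUAL_REASON_TEMPLATES[idx]
            else:
                key = mix_keys[int(rng.choice(len(mix_keys), p=mix_probs))]
                if key == "reason_not_provided":
                    reason_category, reason_text = "reason_not_provided", ""
                elif key == "vague":
                    reason_category = "other"
                    reason_text = VAGUE_TEMPLATES[int(rng.integers(len(VAGUE_TEMPLATES)))]
                else:
                    reason_category = key
                    tpl = REASON_TEMPLATES[key]
                    reason_text = tpl[int(rng.integers(len(tpl)))]
            if rng.random() < config.missing_why_stopped_prob:
                reason_text = ""

        # summary results / publications / cross-registry flags
        sr_prob = config.summary_results_prob.get(group, 0.0)
        has_sr = bool(rng.random() < sr_prob)
        pub_prob = config.publication_prob.get(group, 0.0)
        publications[trial_id] = bool(rng.random() < pub_prob)
        euctr_available = bool((not has_sr) and rng.random() < config.euctr_results_prob)
        euctr_tabular = bool(euctr_available and rng.random() < config.euctr_tabular_prob)

        # corruption knobs
        first_type = EnrollmentType.anticipated
        if rng.random() < config.unmarked_enrollment_prob:
            first_type = EnrollmentType.unmarked
        drop_actual = rng.random() < config.missing_actual_prob

        final_status = {
            "terminated": OverallStatus.terminated,
            "completed": OverallStatus.completed,
            "other": OverallStatus(
                str(rng.choice(["withdrawn", "suspended", "unknown"]))
            ),
        }[group]

        versions = [
            TrialVersion(
                trial_id=trial_id,
                version_date=start,
                version_seq=0,
                overall_status=OverallStatus.recruiting,
                enrollment_count=anticipated,
                enrollment_type=first_type,
                start_date=start,
                primary_completion_date=_int_date(start, planned_duration),
                why_stopped="",
                has_summary_results=False,
            )
        ]
        seq = 1
        if duration > 120:
            versions.append(
                TrialVersion(
                    trial_id=trial_id,
                    version_date=_int_date(start, int(duration * 0.6)),
                    version_seq=seq,
                    overall_status=OverallStatus.active_not_recruiting,
                    enrollment_count=anticipated,
                    enrollment_type=first_type,
                    start_date=start,
                    primary_completion_date=_int_date(start, planned_duration),
                    why_stopped="",
                    has_summary_results=False,
                )
            )
            seq += 1
        versions.append(
            TrialVersion(
                trial_id=trial_id,
                version_date=_int_date(stop, 14),
                version_seq=seq,
                overall_status=final_status,
                enrollment_count=None if drop_actual else actual,
                enrollment_type=EnrollmentType.missing if drop_actual else EnrollmentType.actual,
                start_date=start,
                primary_completion_date=stop,
                why_stopped=reason_text,
                has_summary_results=has_sr,
            )
        )
        histories.append(
            TrialHistory(
                trial_id=trial_id,
                versions=tuple(versions),
                euctr_results_available=euctr_available,
                euctr_results_tabular=euctr_tabular,
            )
        )

        # design
        n_arms = int(rng.choice([1, 2, 3], p=[0.30, 0.55, 0.15]))
        multi = n_arms >= 2
        design = TrialDesign(
            trial_id=trial_id,
            n_arms=n_arms,
            randomized=bool(multi and rng.random() < 0.85),
            crossover=bool(multi and rng.random() < 0.05),
            active_comparator=bool(multi and rng.random() < 0.25),
            any_participant_received_intervention=bool(rng.random() < 0.98),
            phase=PHASES[int(rng.choice(len(PHASES), p=PHASE_PROBS))],
        )
        designs.append(design)

        # MeSH condition terms
        k = int(rng.choice([0, 1, 2, 3], p=[0.10, 0.50, 0.30, 0.10]))
        conditions[trial_id] = sorted(rng.choice(mesh_terms, size=k, replace=False).tolist())

        # arm-level SAE tables (multi-arm trials only)
        theta = None
        if multi:
            sizes = np.maximum(
                5, np.round(sample_law(rng, config.sae.arm_size_law, n_arms))
            ).astype(int)
            p0 = float(np.clip(sample_law(rng, config.sae.baseline_sae_risk_law, 1)[0], 0.005, 0.9))
            theta = config.sae.true_log_rr + config.sae.tau * float(rng.standard_normal())
            p1 = float(min(0.95, p0 * math.exp(theta)))
            arms = [
                ArmSAETable(
                    trial_id=trial_id,
                    arm_id="A0",
                    arm_label="Control",
                    n_at_risk=int(sizes[0]),
                    n_with_sae=int(rng.binomial(int(sizes[0]), p0)),
                )
            ]
            annotations.append(ArmAnnotation(trial_id=trial_id, arm_id="A0", role=ArmRole.control))
            for j in range(1, n_arms):
                arms.append(
                    ArmSAETable(
                        trial_id=trial_id,
                        arm_id=f"A{j}",
                        arm_label=f"Intervention {j}",
                        n_at_risk=int(sizes[j]),
                        n_with_sae=int(rng.binomial(int(sizes[j]), p1)),
                    )
                )
                annotations.append(
                    ArmAnnotation(trial_id=trial_id, arm_id=f"A{j}", role=ArmRole.intervention)
                )
            sae_tables[trial_id] = arms

        truth["trials"][trial_id] = {
            "status_group": group,
            "reason_category": reason_category,
            "reason_text": reason_text,
            "anticipated": anticipated,
            "actual": actual,
            "attainment": attainment,
            "duration_days": duration,
            "sae_log_rr": theta,
        }

    return SyntheticCohort(
        histories=histories,
        designs=designs,
        conditions=conditions,
        sae_tables=sae_tables,
        arm_annotations=annotations,
        publications=publications,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# fixed fixtures


def generate_mesh_fixture() -> MeshTree:
    """A small fixed MeSH tree (~40 terms) spanning the major top-level
    disease branches, including multi-branch terms (e.g. "stroke" sits under
    both the nervous-system and cardiovascular headings). Tree numbers are
    synthetic stand-ins shaped like real ones; "breast cyst" sits under the
    Neoplasms branch so the canonical worked example resolves."""
    terms: dict[str, tuple[str, ...]] = {
        # Neoplasms (C04)
        "breast cyst": ("C04.182.171",),
        "breast neoplasms": ("C04.588.180",),
        "lung neoplasms": ("C04.588.894.797",),
        "leukemia": ("C04.557.337",),
        "lymphoma": ("C04.557.386",),
        "melanoma": ("C04.557.465",),
        "colorectal neoplasms": ("C04.588.274.476",),
        "prostatic neoplasms": ("C04.588.945.440",),
        "glioblastoma": ("C04.557.470.670",),
        # Cardiovascular (C14)
        "hypertension": ("C14.907.489",),
        "myocardial infarction": ("C14.280.647.500",),
        "heart failure": ("C14.280.434",),
        "atrial fibrillation": ("C14.280.067.198",),
        "coronary artery disease": ("C14.280.647.250.260",),
        "stroke": ("C10.228.140.300.775", "C14.907.253.855"),
        # Nervous system (C10)
        "parkinson disease": ("C10.228.662.600",),
        "epilepsy": ("C10.228.140.490",),
        "multiple sclerosis": ("C10.114.375.500", "C20.111.258.250"),
        "migraine disorders": ("C10.228.140.546",),
        "alzheimer disease": ("C10.228.140.380.100",),
        # Infections (C01)
        "hiv infections": ("C01.221.250", "C20.673.480"),
        "pneumonia": ("C01.748.610", "C08.381.677"),
        "sepsis": ("C01.757",),
        "influenza": ("C01.748.310", "C08.730.310"),
        "hepatitis c": ("C01.221.693",),
        # Mental disorders (F03)
        "depressive disorder": ("F03.600.300",),
        "schizophrenia": ("F03.700.750",),
        "anxiety disorders": ("F03.080",),
        "bipolar disorder": ("F03.600.150",),
        "stress disorders, post-traumatic": ("F03.080.931",),
        # Respiratory (C08)
        "asthma": ("C08.127.108",),
        "pulmonary disease, chronic obstructive": ("C08.381.495.389",),
        # Endocrine (C19) / metabolic (C18)
        "diabetes mellitus": ("C19.246",),
        "thyroid diseases": ("C19.874",),
        "obesity": ("C18.654.726.500",),
        # Musculoskeletal / immune / urogenital / skin / congenital
        "osteoarthritis": ("C05.550.114.606",),
        "rheumatoid arthritis": ("C05.550.114.154", "C20.111.199"),
        "renal insufficiency, chronic": ("C12.777.419.780",),
        "psoriasis": ("C17.800.859.675",),
        "cystic fibrosis": ("C08.381.187", "C16.320.190"),
    }
    labels = {
        "C01": "Infections",
        "C04": "Neoplasms",
        "C05": "Musculoskeletal Diseases",
        "C08": "Respiratory Tract Diseases",
        "C10": "Nervous System Diseases",
        "C12": "Urogenital Diseases",
        "C14": "Cardiovascular Diseases",
        "C16": "Congenital, Hereditary, and Neonatal Diseases",
        "C17": "Skin and Connective Tissue Diseases",
        "C18": "Nutritional and Metabolic Diseases",
        "C19": "Endocrine System Diseases",
        "C20": "Immune System Diseases",
        "F03": "Mental Disorders",
    }
    return MeshTree(
        entries={t: frozenset(nums) for t, nums in terms.items()},
        category_labels=labels,
    )


@dataclass
class CascadeFixture:
    histories: list[TrialHistory]
    designs: list[TrialDesign]
    sae_tables: dict[str, list[ArmSAETable]]
    arm_annotations: list[ArmAnnotation]


def generate_cascade_fixture() -> CascadeFixture:
    """Deterministic 76-trial fixture for the SAE eligibility cascade: all
    trials terminated for a non-scientific reason with summary results, of
    which 30 single-arm, 20 active-comparator, 7 non-randomized, 2
    crossover, 2 with no participant receiving an intervention, 1 with
    cross-registry results in non-tabular (PDF-style) form only, and 14
    eligible two-arm randomized parallel trials (11 with registry summary
    results, 3 cross-registry tabular)."""
    rng = np.random.default_rng(76)
    histories: list[TrialHistory] = []
    designs: list[TrialDesign] = []
    sae_tables: dict[str, list[ArmSAETable]] = {}
    annotations: list[ArmAnnotation] = []

    for i in range(1, 77):
        trial_id = f"NCTF{i:04d}"
        start = dt.date(2014, 1, 1) + dt.timedelta(days=3 * i)
        stop = start + dt.timedelta(days=600 + 5 * i)

        # component assignment by index
        if i <= 30:
            kind = "single_arm"
        elif i <= 50:
            kind = "active_comparator"
        elif i <= 57:
            kind = "non_randomized"
        elif i <= 59:
            kind = "crossover"
        elif i <= 61:
            kind = "no_intervention"
        elif i == 62:
            kind = "pdf_only"
        elif i <= 73:
            kind = "eligible_ctgov"
        else:
            kind = "eligible_euctr"

        ctgov_sr = kind not in ("pdf_only", "eligible_euctr")
        euctr_avail = kind in ("pdf_only", "eligible_euctr")
        euctr_tab = kind == "eligible_euctr"

        versions = (
            TrialVersion(
                trial_id=trial_id,
                version_date=start,
                version_seq=0,
                overall_status=OverallStatus.recruiting,
                enrollment_count=120,
                enrollment_type=EnrollmentType.anticipated,
                start_date=start,
                primary_completion_date=start + dt.timedelta(days=900),
                why_stopped="",
                has_summary_results=False,
            ),
            TrialVersion(
                trial_id=trial_id,
                version_date=stop + dt.timedelta(days=14),
                version_seq=1,
                overall_status=OverallStatus.terminated,
                enrollment_count=45,
                enrollment_type=EnrollmentType.actual,
                start_date=start,
                primary_completion_date=stop,
                why_stopped="Terminated due to slow accrual",
                has_summary_results=ctgov_sr,
            ),
        )
        histories.append(
            TrialHistory(
                trial_id=trial_id,
                versions=versions,
                euctr_results_available=euctr_avail,
                euctr_results_tabular=euctr_tab,
            )
        )

        designs.append(
            TrialDesign(
                trial_id=trial_id,
                n_arms=1 if kind == "single_arm" else 2,
                randomized=kind != "non_randomized" and kind != "single_arm",
                crossover=kind == "crossover",
                active_comparator=kind == "active_comparator",
                any_participant_received_intervention=kind != "no_intervention",
                phase=Phase.II,
            )
        )

        if kind in ("eligible_ctgov", "eligible_euctr"):
            n0 = int(40 + rng.integers(0, 60))
            n1 = int(40 + rng.integers(0, 60))
            p0 = 0.08 + 0.1 * rng.random()
            c = int(rng.binomial(n0, p0))
            a = int(rng.binomial(n1, p0))
            sae_tables[trial_id] = [
                ArmSAETable(trial_id=trial_id, arm_id="A0", arm_label="Control",
                            n_at_risk=n0, n_with_sae=c),
                ArmSAETable(trial_id=trial_id, arm_id="A1", arm_label="Intervention",
                            n_at_risk=n1, n_with_sae=a),
            ]
            annotations.append(ArmAnnotation(trial_id=trial_id, arm_id="A0", role=ArmRole.control))
            annotations.append(
                ArmAnnotation(trial_id=trial_id, arm_id="A1", role=ArmRole.intervention)
            )

    return CascadeFixture(
        histories=histories, designs=designs, sae_tables=sae_tables, arm_annotations=annotations
    )


# ---------------------------------------------------------------------------
# on-disk CSV dialects shared with the pipeline


def write_cohort(cohort: SyntheticCohort, out_dir: Union[str, Path]) -> dict[str, Path]:
    """Write a cohort to the CSV dialects the pipeline reads. Returns the
    paths written, keyed by artifact name."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "versions": out / "versions.csv",
        "attributes": out / "trial_attributes.csv",
        "designs": out / "designs.csv",
        "conditions": out / "conditions.csv",
        "sae": out / "sae_arms.csv",
        "annotations": out / "arm_annotations.csv",
        "publications": out / "publications.csv",
        "truth": out / "truth.json",
    }
    write_trial_histories(cohort.histories, paths["versions"], paths["attributes"])
    pd.DataFrame(
        [
            {
                "trial_id": d.trial_id,
                "n_arms": d.n_arms,
                "randomized": str(d.randomized).lower(),
                "crossover": str(d.crossover).lower(),
                "active_comparator": str(d.active_comparator).lower(),
                "any_participant_received_intervention": str(
                    d.any_participant_received_intervention
                ).lower(),
                "phase": d.phase.value,
            }
            for d in sorted(cohort.designs, key=lambda d: d.trial_id)
        ]
    ).to_csv(paths["designs"], index=False, lineterminator="\n")
    pd.DataFrame(
        [
            {"trial_id": t, "mesh_term": term}
            for t in sorted(cohort.conditions)
            for term in cohort.conditions[t]
        ],
        columns=["trial_id", "mesh_term"],
    ).to_csv(paths["conditions"], index=False, lineterminator="\n")
    pd.DataFrame(
        [
            {
                "trial_id": a.trial_id,
                "arm_id": a.arm_id,
                "arm_label": a.arm_label,
                "n_at_risk": a.n_at_risk,
                "n_with_sae": a.n_with_sae,
            }
            for t in sorted(cohort.sae_tables)
            for a in cohort.sae_tables[t]
        ],
        columns=["trial_id", "arm_id", "arm_label", "n_at_risk", "n_with_sae"],
    ).to_csv(paths["sae"], index=False, lineterminator="\n")
    pd.DataFrame(
        [
            {"trial_id": a.trial_id, "arm_id": a.arm_id, "role": a.role.value}
            for a in sorted(cohort.arm_annotations, key=lambda a: (a.trial_id, a.arm_id))
        ],
        columns=["trial_id", "arm_id", "role"],
    ).to_csv(paths["annotations"], index=False, lineterminator="\n")
    pd.DataFrame(
        [
            {"trial_id": t, "has_publication": str(cohort.publications[t]).lower()}
            for t in sorted(cohort.publications)
        ],
        columns=["trial_id", "has_publication"],
    ).to_csv(paths["publications"], index=False, lineterminator="\n")
    paths["truth"].write_text(json.dumps(cohort.truth, indent=2, sort_keys=True), "utf-8")
    return paths


def read_designs(source: Union[str, Path]) -> list[TrialDesign]:
    df = pd.read_csv(source, dtype=str, keep_default_na=False)
    out = []
    for row in df.to_dict("records"):
        out.append(
            TrialDesign(
                trial_id=row["trial_id"],
                n_arms=int(row["n_arms"]),
                randomized=row["randomized"].lower() == "true",
                crossover=row["crossover"].lower() == "true",
                active_comparator=row["active_comparator"].lower() == "true",
                any_participant_received_intervention=row[
                    "any_participant_received_intervention"
                ].lower()
                == "true",
                phase=Phase(row["phase"]),
            )
        )
    return out


def read_conditions(source: Union[str, Path]) -> dict[str, list[str]]:
    df = pd.read_csv(source, dtype=str, keep_default_na=False)
    out: dict[str, list[str]] = {}
    for row in df.to_dict("records"):
        out.setdefault(row["trial_id"], []).append(row["mesh_term"])
    return out


def read_sae_tables(source: Union[str, Path]) -> dict[str, list[ArmSAETable]]:
    df = pd.read_csv(source, dtype=str, keep_default_na=False)
    out: dict[str, list[ArmSAETable]] = {}
    for row in df.to_dict("records"):
        out.setdefault(row["trial_id"], []).append(
            ArmSAETable(
                trial_id=row["trial_id"],
                arm_id=row["arm_id"],
                arm_label=row["arm_label"],
                n_at_risk=int(row["n_at_risk"]),
                n_with_sae=int(row["n_with_sae"]),
            )
        )
    return out


def read_arm_annotations(source: Union[str, Path]) -> list[ArmAnnotation]:
    df = pd.read_csv(source, dtype=str, keep_default_na=False)
    return [
        ArmAnnotation(trial_id=row["trial_id"], arm_id=row["arm_id"], role=ArmRole(row["role"]))
        for row in df.to_dict("records")
    ]


def read_publications(source: Union[str, Path]) -> dict[str, bool]:
    df = pd.read_csv(source, dtype=str, keep_default_na=False)
    return {
        row["trial_id"]: row["has_publication"].lower() == "true" for row in df.to_dict("records")
    }
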