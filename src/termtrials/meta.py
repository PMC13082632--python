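"""SAE risk meta-analysis for trials terminated for non-scientific reasons.

Given arm-level serious-adverse-event counts from registry results tables
and a manual arm-role annotation (registry arm identifiers such as "EG000"
are unreliable and never trusted as roles), each eligible trial is collapsed
to a 2×2 table — participants with ≥1 SAE vs at risk, intervention vs
control — and per-trial risk ratios are pooled on the log scale.

Pooling follows standard practice for binary outcomes:

* common-effect (fixed-effect): inverse-variance weights ``w_i = 1/se_i²``;
* random-effects: DerSimonian–Laird moment estimate of the between-trial
  variance τ² (REML available as an option), weights ``1/(se_i² + τ²)``;
* heterogeneity: Cochran's Q and ``I² = max(0, (Q − (k−1))/Q) × 100``;
* sparse data: a 0.5 continuity correction added to every 2×2 cell when
  exactly one event cell is zero; double-zero trials carry no information
  about the risk ratio and are excluded from RR pooling (their risk
  difference, 0, is still recorded);
* 95% z-based (Wald) confidence intervals on the log-RR scale.

Eligibility is an ordered cascade; each candidate is attributed to the
first filter it fails, yielding PRISMA-style exclusion counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .registry import TrialDesign

Z_95 = 1.959964


class ArmRole(str, Enum):
    control = "control"
    intervention = "intervention"
    other = "other"


@dataclass(frozen=True)
class ArmSAETable:
    """One arm's SAE row from a registry results table."""

    trial_id: str
    arm_id: str
    arm_label: str
    n_at_risk: int
    n_with_sae: int

    def __post_init__(self):
        if not (0 <= self.n_with_sae <= self.n_at_risk):
            raise ValueError(
                f"{self.trial_id}/{self.arm_id}: n_with_sae must lie in [0, n_at_risk]"
            )


@dataclass(frozen=True)
class ArmAnnotation:
    trial_id: str
    arm_id: str
    role: ArmRole


@dataclass(frozen=True)
class TwoByTwo:
    """Collapsed intervention-vs-control SAE table for one trial."""

    trial_id: str
    a: int  # events, intervention
    n1: int  # at risk, intervention
    c: int  # events, control
    n2: int  # at risk, control
    continuity_applied: bool = False

    def __post_init__(self):
        if self.n1 <= 0 or self.n2 <= 0:
            raise ValueError(f"{self.trial_id}: both arms need participants at risk")
        if not (0 <= self.a <= self.n1 and 0 <= self.c <= self.n2):
            raise ValueError(f"{self.trial_id}: cell counts exceed participants at risk")


@dataclass
class StudyEffect:
    """Per-trial risk ratio (log scale, with SE) and risk difference."""

    trial_id: str
    rr: Optional[float]
    log_rr: Optional[float]
    se_log_rr: Optional[float]
    rd: float
    continuity_applied: bool = False
    excluded_zero_both: bool = False


@dataclass
class HeterogeneityResult:
    q_stat: float
    tau2: float
    i2_pct: float


@dataclass
class PooledResult:
    model: str  # common_effect | random_effects
    k: int
    rr_pooled: float
    ci_low: float
    ci_high: float
    p_value: float
    q_stat: float
    tau2: float
    i2_pct: float
    weights: dict[str, float]  # normalized, sum to 1

    @property
    def log_rr_pooled(self) -> float:
        return math.log(self.rr_pooled)

    @property
    def se_log_rr(self) -> float:
        return (math.log(self.ci_high) - math.log(self.ci_low)) / (2 * Z_95)


EXCLUSION_REASONS = (
    "single_arm",
    "active_comparator",
    "non_randomized",
    "crossover",
    "no_intervention_administered",
    "non_tabular_cross_registry",
)


@dataclass
class EligibilityResult:
    """PRISMA-style cascade outcome: candidate funnel plus per-filter
    exclusion counts (``metadata_missing`` collects candidates whose design
    record is absent — never silently included)."""

    n_candidates: int
    n_with_tabular_results: int
    exclusions: dict[str, int]
    included_trial_ids: list[str]
    excluded_by_trial: dict[str, str] = field(default_factory=dict)


@dataclass(frozen=True)
class CascadeRecord:
    """Joined per-trial inputs the cascade consumes."""

    trial_id: str
    reason_class: str  # scientific | non_scientific | not_provided | other
    summary_results: str  # ctgov | euctr_only | none
    euctr_results_tabular: bool = False
    design: Optional[TrialDesign] = None


class ArmAssignmentError(Exception):
    pass


class AnnotationMissingError(Exception):
    pass


def eligibility_cascade(records: Sequence[CascadeRecord]) -> EligibilityResult:
    """Apply the eligibility filters in fixed order, attributing every
    excluded candidate to the first filter it fails.

    Candidates are trials terminated for non-scientific reasons; of those,
    the funnel keeps trials with summary results available, then excludes in
    order: single-arm, active comparator, non-randomized, crossover, no
    participant received an intervention, and cross-registry-only results
    not available in structured tabular form.
    """
    candidates = [r for r in records if r.reason_class == "non_scientific"]
    with_results = [r for r in candidates if r.summary_results != "none"]

    exclusions = {reason: 0 for reason in EXCLUSION_REASONS}
    exclusions["metadata_missing"] = 0
    included: list[str] = []
    excluded_by_trial: dict[str, str] = {}

    for r in with_results:
        if r.design is None:
            reason = "metadata_missing"
        elif r.design.n_arms < 2:
            reason = "single_arm"
        elif r.design.active_comparator:
            reason = "active_comparator"
        elif not r.design.randomized:
            reason = "non_randomized"
        elif r.design.crossover:
            reason = "crossover"
        elif not r.design.any_participant_received_intervention:
            reason = "no_intervention_administered"
        elif r.summary_results == "euctr_only" and not r.euctr_results_tabular:
            reason = "non_tabular_cross_registry"
        else:
            included.append(r.trial_id)
            continue
        exclusions[reason] += 1
        excluded_by_trial[r.trial_id] = reason

    return EligibilityResult(
        n_candidates=len(candidates),
        n_with_tabular_results=len(with_results),
        exclusions=exclusions,
        included_trial_ids=included,
        excluded_by_trial=excluded_by_trial,
    )


def build_two_by_two(
    arms: Sequence[ArmSAETable], annotations: Sequence[ArmAnnotation]
) -> TwoByTwo:
    """Collapse annotated arms into a 2×2: multiple intervention arms are
    summed into one column; exactly one control arm is required; any arm
    with role ``other`` makes the trial ineligible (ambiguous assignment is
    an error, not a guess)."""
    if not arms:
        raise ValueError("no arms supplied")
    trial_id = arms[0].trial_id
    roles = {(a.trial_id, a.arm_id): a.role for a in annotations}
    a = n1 = c = n2 = 0
    n_control = 0
    for arm in arms:
        role = roles.get((arm.trial_id, arm.arm_id))
        if role is None:
            raise AnnotationMissingError(f"{arm.trial_id}/{arm.arm_id}: no arm-role annotation")
        if role == ArmRole.other:
            raise ArmAssignmentError(
                f"{arm.trial_id}/{arm.arm_id}: role 'other' cannot be assigned to a 2x2"
            )
        if role == ArmRole.control:
            n_control += 1
            c, n2 = arm.n_with_sae, arm.n_at_risk
        else:
            a += arm.n_with_sae
            n1 += arm.n_at_risk
    if n_control != 1:
        raise ArmAssignmentError(f"{trial_id}: need exactly one control arm, got {n_control}")
    if n1 == 0:
        raise ArmAssignmentError(f"{trial_id}: no intervention arm")
    return TwoByTwo(trial_id=trial_id, a=a, n1=n1, c=c, n2=n2)


def study_effect(t: TwoByTwo) -> StudyEffect:
    """Per-trial risk ratio and risk difference.

    With exactly one zero event cell, 0.5 is added to each of the four 2×2
    cells before computing RR and its SE; the risk difference always uses
    the uncorrected counts. With both event cells zero the RR is not
    estimable and the study is marked ``excluded_zero_both``.
    """
    rd = t.a / t.n1 - t.c / t.n2
    if t.a == 0 and t.c == 0:
        return StudyEffect(
            trial_id=t.trial_id, rr=None, log_rr=None, se_log_rr=None, rd=rd,
            excluded_zero_both=True,
        )
    if t.a == 0 or t.c == 0:
        a, c = t.a + 0.5, t.c + 0.5
        n1, n2 = t.n1 + 1.0, t.n2 + 1.0
        continuity = True
    else:
        a, c, n1, n2 = float(t.a), float(t.c), float(t.n1), float(t.n2)
        continuity = False
    rr = (a / n1) / (c / n2)
    se = math.sqrt(1 / a - 1 / n1 + 1 / c - 1 / n2)
    return StudyEffect(
        trial_id=t.trial_id, rr=rr, log_rr=math.log(rr), se_log_rr=se, rd=rd,
        continuity_applied=continuity,
    )


def _estimable(effects: Sequence[StudyEffect]) -> list[StudyEffect]:
    return [e for e in effects if not e.excluded_zero_both]


def _pool(effects: list[StudyEffect], weights: np.ndarray, model: str,
          q: float, tau2: float, i2: float) -> PooledResult:
    log_rrs = np.array([e.log_rr for e in effects])
    wsum = weights.sum()
    pooled = float((weights * log_rrs).sum() / wsum)
    se = float(1.0 / math.sqrt(wsum))
    z = pooled / se
    p = float(2 * stats.norm.sf(abs(z)))
    return PooledResult(
        model=model,
        k=len(effects),
        rr_pooled=math.exp(pooled),
        ci_low=math.exp(pooled - Z_95 * se),
        ci_high=math.exp(pooled + Z_95 * se),
        p_value=p,
        q_stat=q,
        tau2=tau2,
        i2_pct=i2,
        weights={e.trial_id: float(w / wsum) for e, w in zip(effects, weights)},
    )


def heterogeneity(effects: Sequence[StudyEffect]) -> HeterogeneityResult:
    """Cochran's Q, DerSimonian–Laird τ², and I² from the estimable studies.
    With fewer than two studies all three are 0 by convention."""
    effects = _estimable(effects)
    k = len(effects)
    if k < 2:
        return HeterogeneityResult(q_stat=0.0, tau2=0.0, i2_pct=0.0)
    w = np.array([1.0 / e.se_log_rr**2 for e in effects])
    y = np.array([e.log_rr for e in effects])
    mu = (w * y).sum() / w.sum()
    q = float((w * (y - mu) ** 2).sum())
    denom = w.sum() - (w**2).sum() / w.sum()
    tau2 = max(0.0, (q - (k - 1)) / denom) if denom > 0 else 0.0
    i2 = max(0.0, (q - (k - 1)) / q) * 100.0 if q > 0 else 0.0
    return HeterogeneityResult(q_stat=q, tau2=tau2, i2_pct=i2)


def _tau2_reml(effects: Sequence[StudyEffect]) -> float:
    """Restricted maximum-likelihood τ² (profile over the pooled mean)."""
    y = np.array([e.log_rr for e in effects])
    v = np.array([e.se_log_rr**2 for e in effects])

    def neg_restricted_ll(tau2: float) -> float:
        w = 1.0 / (v + tau2)
        mu = (w * y).sum() / w.sum()
        return 0.5 * (np.log(v + tau2).sum() + (w * (y - mu) ** 2).sum() + math.log(w.sum()))

    res = optimize.minimize_scalar(neg_restricted_ll, bounds=(0.0, 10.0 * (y.var() + v.max())),
                                   method="bounded")
    return float(max(0.0, res.x))


def pool_common_effect(effects: Sequence[StudyEffect]) -> PooledResult:
    """Inverse-variance common-effect (fixed-effect) pooling on log RR."""
    est = _estimable(effects)
    if not est:
        raise ValueError("no estimable study effects to pool")
    het = heterogeneity(est)
    w = np.array([1.0 / e.se_log_rr**2 for e in est])
    return _pool(est, w, "common_effect", het.q_stat, 0.0, het.i2_pct)


def pool_random_effects(
    effects: Sequence[StudyEffect], tau2_method: str = "dl"
) -> PooledResult:
    """Random-effects pooling with DerSimonian–Laird τ² (or REML via
    ``tau2_method="reml"``). With τ² = 0 the result coincides with the
    common-effect model component-wise."""
    est = _estimable(effects)
    if not est:
        raise ValueError("no estimable study effects to pool")
    het = heterogeneity(est)
    if tau2_method == "dl":
        tau2 = het.tau2
    elif tau2_method == "reml":
        tau2 = _tau2_reml(est) if len(est) >= 2 else 0.0
    else:
        raise ValueError(f"unknown tau2 method: {tau2_method!r}")
    w = np.array([1.0 / (e.se_log_rr**2 + tau2) for e in est])
    return _pool(est, w, "random_effects", het.q_stat, tau2, het.i2_pct)


def pool_mantel_haenszel(tables: Sequence[TwoByTwo]) -> PooledResult:
    """Mantel–Haenszel pooled risk ratio (alternative common-effect
    estimator for binary data), with Greenland–Robins variance. Double-zero
    tables contribute nothing and are skipped."""
    tabs = [t for t in tables if not (t.a == 0 and t.c == 0)]
    if not tabs:
        raise ValueError("no informative 2x2 tables")
    R = S = 0.0
    num = den1 = den2 = 0.0
    for t in tabs:
        n = t.n1 + t.n2
        R += t.a * t.n2 / n
        S += t.c * t.n1 / n
        num += (t.a + t.c) * t.n1 * t.n2 / n**2 - t.a * t.c / n
        den1 += t.a * t.n2 / n
        den2 += t.c * t.n1 / n
    rr = R / S
    se = math.sqrt(num / (den1 * den2))
    log_rr = math.log(rr)
    z = log_rr / se
    effects = [study_effect(t) for t in tabs]
    het = heterogeneity(effects)
    # MH weights for RR are the control-arm contributions S_i
    w = np.array([t.c * t.n1 / (t.n1 + t.n2) for t in tabs])
    if w.sum() == 0:
        w = np.ones(len(tabs))
    wsum = w.sum()
    return PooledResult(
        model="mantel_haenszel",
        k=len(tabs),
        rr_pooled=rr,
        ci_low=math.exp(log_rr - Z_95 * se),
        ci_high=math.exp(log_rr + Z_95 * se),
        p_value=float(2 * stats.norm.sf(abs(z))),
        q_stat=het.q_stat,
        tau2=0.0,
        i2_pct=het.i2_pct,
        weights={t.trial_id: float(x / wsum) for t, x in zip(tabs, w)},
    )


def forest_data(
    effects: Sequence[StudyEffect],
    pooled_common: PooledResult,
    pooled_random: PooledResult,
) -> pd.DataFrame:
    """Forest-plot row table: one row per estimable study (RR, 95% CI,
    normalized weight under each model) plus the two pooled summary rows."""
    rows = []
    for e in _estimable(effects):
        rows.append(
            {
                "row_type": "study",
                "trial_id": e.trial_id,
                "rr": e.rr,
                "ci_low": math.exp(e.log_rr - Z_95 * e.se_log_rr),
                "ci_high": math.exp(e.log_rr + Z_95 * e.se_log_rr),
                "weight_common_pct": 100.0 * pooled_common.weights[e.trial_id],
                "weight_random_pct": 100.0 * pooled_random.weights[e.trial_id],
            }
        )
    for pooled in (pooled_common, pooled_random):
        rows.append(
            {
                "row_type": f"pooled_{pooled.model}",
                "trial_id": "",
                "rr": pooled.rr_pooled,
                "ci_low": pooled.ci_low,
                "ci_high": pooled.ci_high,
                "weight_common_pct": float("nan"),
                "weight_random_pct": float("nan"),
            }
        )
    return pd.DataFrame(rows)


def plot_forest(df: pd.DataFrame, destination) -> None:
    """Render a forest-plot image from :func:`forest_data` output."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    n = len(df)
    fig, ax = plt.subplots(figsize=(7, 0.45 * n + 1.5))
    ys = range(n - 1, -1, -1)
    for y, (_, row) in zip(ys, df.iterrows()):
        marker = "D" if str(row["row_type"]).startswith("pooled") else "s"
        ax.plot([row["ci_low"], row["ci_high"]], [y, y], color="k", lw=1)
        ax.plot(row["rr"], y, marker, color="k", ms=6)
    ax.axvline(1.0, color="grey", ls="--", lw=0.8)
    ax.set_xscale("log")
    ax.set_yticks(list(ys))
    labels = [
        row["trial_id"] if row["row_type"] == "study" else row["row_type"]
        for _, row in df.iterrows()
    ]
    ax.set_yticklabels(labels, fontsize=8)
    ax.set_xlabel("Risk ratio (intervention vs control), 95% CI")
    fig.tight_layout()
    fig.savefig(destination, dpi=120)
    plt.close(fig)


def effects_to_frame(effects: Sequence[StudyEffect]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "trial_id": [e.trial_id for e in effects],
            "rr": [e.rr for e in effects],
            "log_rr": [e.log_rr for e in effects],
            "se_log_rr": [e.se_log_rr for e in effects],
            "rd": [e.rd for e in effects],
            "continuity_applied": [e.continuity_applied for e in effects],
            "excluded_zero_both": [e.excluded_zero_both for e in effects],
        }
    )


def pooled_to_dict(p: PooledResult) -> dict:
    return {
        "model": p.model,
        "k": p.k,
        "rr": p.rr_pooled,
        "ci_low": p.ci_low,
        "ci_high": p.ci_high,
        "p_value": p.p_value,
        "q": p.q_stat,
        "tau2": p.tau2,
        "i2_pct": p.i2_pct,
        "weights": {k: p.weights[k] for k in sorted(p.weights)},
    }
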