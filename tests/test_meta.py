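"""SAE eligibility cascade, 2x2 construction, risk-ratio pooling and
heterogeneity."""

import math

import numpy as np
import pytest

from termtrials.meta import (
    AnnotationMissingError,
    ArmAnnotation,
    ArmAssignmentError,
    ArmRole,
    ArmSAETable,
    CascadeRecord,
    StudyEffect,
    TwoByTwo,
    build_two_by_two,
    eligibility_cascade,
    forest_data,
    heterogeneity,
    pool_common_effect,
    pool_mantel_haenszel,
    pool_random_effects,
    study_effect,
)
from termtrials.registry import TrialDesign


def design(trial_id="T", n_arms=2, randomized=True, crossover=False,
           active_comparator=False, intervention=True):
    return TrialDesign(
        trial_id=trial_id, n_arms=n_arms, randomized=randomized, crossover=crossover,
        active_comparator=active_comparator,
        any_participant_received_intervention=intervention,
    )


class TestEligibilityCascade:
    def test_scientific_reason_never_becomes_candidate(self):
        rec = CascadeRecord("T1", "scientific", "ctgov", design=design("T1"))
        result = eligibility_cascade([rec])
        assert result.n_candidates == 0 and result.included_trial_ids == []

    def test_first_failing_filter_attribution(self):
        # single-arm AND non-randomized: attributed to single_arm only
        rec = CascadeRecord(
            "T1", "non_scientific", "ctgov",
            design=design("T1", n_arms=1, randomized=False),
        )
        result = eligibility_cascade([rec])
        assert result.exclusions["single_arm"] == 1
        assert result.exclusions["non_randomized"] == 0

    def test_missing_design_goes_to_metadata_bucket_never_included(self):
        rec = CascadeRecord("T1", "non_scientific", "ctgov", design=None)
        result = eligibility_cascade([rec])
        assert result.exclusions["metadata_missing"] == 1
        assert result.included_trial_ids == []

    def test_cross_registry_pdf_only_results_excluded_last(self):
        rec = CascadeRecord(
            "T1", "non_scientific", "euctr_only", euctr_results_tabular=False,
            design=design("T1"),
        )
        result = eligibility_cascade([rec])
        assert result.exclusions["non_tabular_cross_registry"] == 1

    def test_funnel_invariant_holds(self):
        recs = [
            CascadeRecord("A", "non_scientific", "ctgov", design=design("A")),
            CascadeRecord("B", "non_scientific", "none", design=design("B")),
            CascadeRecord("C", "non_scientific", "ctgov", design=design("C", n_arms=1)),
            CascadeRecord("D", "not_provided", "ctgov", design=design("D")),
        ]
        r = eligibility_cascade(recs)
        assert r.n_candidates == 3
        assert r.n_with_tabular_results == 2
        assert r.n_with_tabular_results - sum(r.exclusions.values()) == len(r.included_trial_ids)


class TestTwoByTwo:
    def test_simple_two_arm_collapse(self):
        arms = [
            ArmSAETable("T", "I1", "Drug", 100, 10),
            ArmSAETable("T", "C1", "Placebo", 100, 5),
        ]
        anns = [
            ArmAnnotation("T", "I1", ArmRole.intervention),
            ArmAnnotation("T", "C1", ArmRole.control),
        ]
        t = build_two_by_two(arms, anns)
        assert (t.a, t.n1, t.c, t.n2) == (10, 100, 5, 100)

    def test_multiple_intervention_arms_are_summed(self):
        arms = [
            ArmSAETable("T", "I1", "Dose A", 50, 3),
            ArmSAETable("T", "I2", "Dose B", 50, 2),
            ArmSAETable("T", "C1", "Placebo", 100, 4),
        ]
        anns = [
            ArmAnnotation("T", "I1", ArmRole.intervention),
            ArmAnnotation("T", "I2", ArmRole.intervention),
            ArmAnnotation("T", "C1", ArmRole.control),
        ]
        t = build_two_by_two(arms, anns)
        assert (t.a, t.n1) == (3 + 2, 50 + 50)
        assert (t.c, t.n2) == (4, 100)

    def test_role_other_is_an_error(self):
        arms = [ArmSAETable("T", "X", "?", 50, 1), ArmSAETable("T", "C", "ctl", 50, 1)]
        anns = [
            ArmAnnotation("T", "X", ArmRole.other),
            ArmAnnotation("T", "C", ArmRole.control),
        ]
        with pytest.raises(ArmAssignmentError):
            build_two_by_two(arms, anns)

    def test_unannotated_arm_is_an_error(self):
        arms = [ArmSAETable("T", "I1", "Drug", 50, 1)]
        with pytest.raises(AnnotationMissingError):
            build_two_by_two(arms, [])

    @pytest.mark.parametrize("n_controls", [0, 2])
    def test_exactly_one_control_required(self, n_controls):
        arms = [ArmSAETable("T", f"A{i}", "", 50, 1) for i in range(3)]
        roles = [ArmRole.control] * n_controls + [ArmRole.intervention] * (3 - n_controls)
        anns = [ArmAnnotation("T", f"A{i}", r) for i, r in enumerate(roles)]
        with pytest.raises(ArmAssignmentError):
            build_two_by_two(arms, anns)

    def test_event_count_cannot_exceed_at_risk(self):
        with pytest.raises(ValueError):
            ArmSAETable("T", "A", "", 10, 11)


class TestStudyEffect:
    def test_direct_arithmetic(self):
        e = study_effect(TwoByTwo("T", a=10, n1=100, c=5, n2=100))
        assert e.rr == pytest.approx(2.0)
        assert e.rd == pytest.approx(0.05)
        assert e.se_log_rr == pytest.approx(
            math.sqrt(1 / 10 - 1 / 100 + 1 / 5 - 1 / 100)
        )

    def test_symmetry_gives_null_effect(self):
        e = study_effect(TwoByTwo("T", a=7, n1=50, c=7, n2=50))
        assert e.rr == pytest.approx(1.0) and e.log_rr == pytest.approx(0.0)

    def test_single_zero_cell_continuity_hand_oracle(self):
        e = study_effect(TwoByTwo("T", a=0, n1=50, c=3, n2=50))
        assert e.continuity_applied
        assert e.rr == pytest.approx((0.5 / 51) / (3.5 / 51))
        assert e.se_log_rr == pytest.approx(
            math.sqrt(1 / 0.5 - 1 / 51 + 1 / 3.5 - 1 / 51)
        )
        # risk difference stays on uncorrected counts
        assert e.rd == pytest.approx(0 / 50 - 3 / 50)

    def test_double_zero_not_estimable_but_rd_kept(self):
        e = study_effect(TwoByTwo("T", a=0, n1=50, c=0, n2=60))
        assert e.excluded_zero_both and e.rr is None and e.rd == 0.0

    def test_empty_arm_rejected(self):
        with pytest.raises(ValueError):
            TwoByTwo("T", a=0, n1=0, c=1, n2=10)


def _random_effects_set(rng, k):
    return [
        StudyEffect(
            trial_id=f"S{i}",
            rr=None, log_rr=float(rng.normal(0, 0.5)),
            se_log_rr=float(rng.uniform(0.1, 0.8)), rd=0.0,
        )
        for i in range(k)
    ]


class TestPooling:
    def test_single_study_pooling_is_identity(self):
        e = study_effect(TwoByTwo("T", a=10, n1=100, c=5, n2=100))
        pooled = pool_common_effect([e])
        assert pooled.rr_pooled == pytest.approx(e.rr)
        assert pooled.ci_low == pytest.approx(math.exp(e.log_rr - 1.959964 * e.se_log_rr))
        pooled_re = pool_random_effects([e])
        assert pooled_re.rr_pooled == pytest.approx(e.rr)

    def test_two_identical_studies_halve_the_variance(self):
        e = StudyEffect("A", rr=None, log_rr=0.3, se_log_rr=0.2, rd=0.0)
        f = StudyEffect("B", rr=None, log_rr=0.3, se_log_rr=0.2, rd=0.0)
        pooled = pool_common_effect([e, f])
        assert pooled.log_rr_pooled == pytest.approx(0.3)
        assert pooled.se_log_rr == pytest.approx(0.2 / math.sqrt(2), rel=1e-6)

    def test_bruteforce_inverse_variance_oracle(self):
        rng = np.random.default_rng(11)
        effects = _random_effects_set(rng, 5)
        pooled = pool_common_effect(effects)
        w = [1 / e.se_log_rr**2 for e in effects]
        mu = sum(wi * e.log_rr for wi, e in zip(w, effects)) / sum(w)
        assert pooled.log_rr_pooled == pytest.approx(mu, abs=1e-12)
        assert sum(pooled.weights.values()) == pytest.approx(1.0, abs=1e-9)

    def test_matches_statsmodels_combine_effects(self):
        sm_meta = pytest.importorskip("statsmodels.stats.meta_analysis")
        rng = np.random.default_rng(23)
        effects = _random_effects_set(rng, 8)
        eff = np.array([e.log_rr for e in effects])
        var = np.array([e.se_log_rr**2 for e in effects])
        res = sm_meta.combine_effects(eff, var, method_re="dl")
        ours_fe = pool_common_effect(effects)
        ours_re = pool_random_effects(effects)
        het = heterogeneity(effects)
        assert ours_fe.log_rr_pooled == pytest.approx(res.mean_effect_fe, abs=1e-10)
        assert het.q_stat == pytest.approx(res.q, abs=1e-10)
        if res.tau2 > 0:
            assert het.tau2 == pytest.approx(res.tau2, abs=1e-10)
            assert ours_re.log_rr_pooled == pytest.approx(res.mean_effect_re, abs=1e-10)

    def test_study_order_permutation_invariance(self):
        rng = np.random.default_rng(3)
        effects = _random_effects_set(rng, 6)
        a = pool_random_effects(effects)
        b = pool_random_effects(list(reversed(effects)))
        assert a.rr_pooled == pytest.approx(b.rr_pooled, abs=1e-12)
        assert a.tau2 == pytest.approx(b.tau2, abs=1e-12)
        assert a.weights == pytest.approx(b.weights)

    def test_common_effect_se_not_larger_than_best_study(self):
        rng = np.random.default_rng(9)
        effects = _random_effects_set(rng, 7)
        pooled = pool_common_effect(effects)
        assert pooled.se_log_rr <= min(e.se_log_rr for e in effects) + 1e-12

    def test_zero_both_studies_are_inert(self):
        rng = np.random.default_rng(4)
        effects = _random_effects_set(rng, 5)
        zz = study_effect(TwoByTwo("ZZ", a=0, n1=40, c=0, n2=40))
        with_zz = pool_random_effects(effects + [zz])
        without = pool_random_effects(effects)
        assert with_zz.rr_pooled == pytest.approx(without.rr_pooled, abs=1e-15)
        assert with_zz.k == without.k

    def test_random_effects_ci_at_least_as_wide_when_heterogeneous(self):
        effects = [
            StudyEffect("A", None, 1.0, 0.1, 0.0),
            StudyEffect("B", None, -1.0, 0.1, 0.0),
            StudyEffect("C", None, 0.5, 0.1, 0.0),
        ]
        het = heterogeneity(effects)
        assert het.tau2 > 0
        ce = pool_common_effect(effects)
        re = pool_random_effects(effects)
        assert (re.ci_high / re.ci_low) > (ce.ci_high / ce.ci_low)

    def test_empty_pool_is_an_error(self):
        with pytest.raises(ValueError):
            pool_common_effect([])

    def test_reml_tau2_close_to_dl_on_mild_heterogeneity(self):
        rng = np.random.default_rng(17)
        effects = _random_effects_set(rng, 10)
        re_dl = pool_random_effects(effects, tau2_method="dl")
        re_reml = pool_random_effects(effects, tau2_method="reml")
        assert re_reml.tau2 >= 0
        assert re_reml.rr_pooled == pytest.approx(re_dl.rr_pooled, rel=0.2)


class TestHeterogeneity:
    def test_identical_studies_are_homogeneous(self):
        e = StudyEffect("A", None, 0.2, 0.3, 0.0)
        effects = [e, StudyEffect("B", None, 0.2, 0.3, 0.0)]
        het = heterogeneity(effects)
        assert het.q_stat == pytest.approx(0.0)
        assert het.tau2 == 0.0 and het.i2_pct == 0.0

    def test_fewer_than_two_studies_by_convention_zero(self):
        het = heterogeneity([StudyEffect("A", None, 0.2, 0.3, 0.0)])
        assert (het.q_stat, het.tau2, het.i2_pct) == (0.0, 0.0, 0.0)

    def test_q_below_df_truncates_to_zero(self):
        effects = [
            StudyEffect("A", None, 0.20, 0.5, 0.0),
            StudyEffect("B", None, 0.21, 0.5, 0.0),
            StudyEffect("C", None, 0.19, 0.5, 0.0),
        ]
        het = heterogeneity(effects)
        assert het.q_stat < 2 and het.tau2 == 0.0 and het.i2_pct == 0.0

    def test_q_matches_bruteforce_summation(self):
        rng = np.random.default_rng(21)
        effects = _random_effects_set(rng, 6)
        het = heterogeneity(effects)
        w = [1 / e.se_log_rr**2 for e in effects]
        mu = sum(wi * e.log_rr for wi, e in zip(w, effects)) / sum(w)
        q = sum(wi * (e.log_rr - mu) ** 2 for wi, e in zip(w, effects))
        assert het.q_stat == pytest.approx(q, abs=1e-12)


class TestMantelHaenszel:
    def test_single_table_equals_crude_rr(self):
        t = TwoByTwo("T", a=10, n1=100, c=5, n2=100)
        pooled = pool_mantel_haenszel([t])
        assert pooled.rr_pooled == pytest.approx(2.0)

    def test_equal_strata_pool_to_common_rr(self):
        t = TwoByTwo("T1", a=10, n1=100, c=5, n2=100)
        u = TwoByTwo("T2", a=10, n1=100, c=5, n2=100)
        pooled = pool_mantel_haenszel([t, u])
        assert pooled.rr_pooled == pytest.approx(2.0)


class TestForest:
    def test_three_studies_make_five_rows_with_weights_summing_100(self):
        tables = [
            TwoByTwo("A", 10, 100, 5, 100),
            TwoByTwo("B", 8, 90, 9, 95),
            TwoByTwo("C", 2, 40, 4, 45),
        ]
        effects = [study_effect(t) for t in tables]
        ce, re = pool_common_effect(effects), pool_random_effects(effects)
        df = forest_data(effects, ce, re)
        assert len(df) == 5
        studies = df[df.row_type == "study"]
        assert studies["weight_common_pct"].sum() == pytest.approx(100.0)
        assert studies["weight_random_pct"].sum() == pytest.approx(100.0)
        # row CIs match recomputation from each study's SE
        for (_, row), e in zip(studies.iterrows(), effects):
            assert row["ci_low"] == pytest.approx(
                math.exp(e.log_rr - 1.959964 * e.se_log_rr)
            )

    def test_forest_plot_renders(self, tmp_path):
        from termtrials.meta import plot_forest

        tables = [TwoByTwo("A", 10, 100, 5, 100), TwoByTwo("B", 8, 90, 9, 95)]
        effects = [study_effect(t) for t in tables]
        df = forest_data(effects, pool_common_effect(effects), pool_random_effects(effects))
        out = tmp_path / "forest.png"
        plot_forest(df, out)
        assert out.stat().st_size > 0
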