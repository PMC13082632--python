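"""Version-specific variable derivation: degree of enrollment, trial days,
summary-results availability."""

import pytest

from termtrials.derivation import (
    FLAG_EXCLUDED_UNCLEAR,
    FLAG_NEGATIVE_DURATION,
    FLAG_NO_ACTUAL,
    FLAG_NO_TERMINATED_VERSION,
    FLAG_NO_VERSION_ON_OR_AFTER_START,
    FLAG_UNMARKED_ASSIGNED,
    aggregate_degree_of_enrollment,
    derive_degree_of_enrollment,
    derive_summary_results,
    derive_trial_days,
    derive_variables,
)
from termtrials.registry import EnrollmentType, OverallStatus, TrialHistory

from conftest import make_history, make_version


def terminated_history(anticipated, actual, trial_id="NCT00000001"):
    return make_history(
        make_version(trial_id=trial_id, version_seq=0, enrollment=anticipated,
                     start_date="2012-01-01", pcd="2014-01-01"),
        make_version(trial_id=trial_id, version_date="2013-06-01", version_seq=1,
                     status=OverallStatus.terminated, enrollment=actual,
                     enrollment_type=EnrollmentType.actual,
                     start_date="2012-01-01", pcd="2013-05-01"),
    )


class TestDegreeOfEnrollment:
    @pytest.mark.parametrize(
        "anticipated,actual,expected",
        [(100, 39, 39.0), (80, 96, 120.0), (50, 50, 100.0)],
    )
    def test_ratio_definition(self, anticipated, actual, expected):
        d = derive_degree_of_enrollment(terminated_history(anticipated, actual))
        assert d.degree_of_enrollment_pct == pytest.approx(expected)

    def test_no_actual_version_means_missing_with_flags(self):
        h = make_history(
            make_version(version_seq=0, enrollment=100, start_date="2012-01-01")
        )
        d = derive_degree_of_enrollment(h)
        assert d.degree_of_enrollment_pct is None
        assert {FLAG_NO_ACTUAL, FLAG_EXCLUDED_UNCLEAR} <= d.flags

    def test_unmarked_enrollment_accepted_as_anticipated_and_flagged(self):
        h = make_history(
            make_version(version_seq=0, enrollment=100,
                         enrollment_type=EnrollmentType.unmarked, start_date="2012-01-01"),
            make_version(version_date="2013-01-01", version_seq=1, enrollment=30,
                         enrollment_type=EnrollmentType.actual),
        )
        d = derive_degree_of_enrollment(h)
        assert d.anticipated_enrollment == 100
        assert d.degree_of_enrollment_pct == pytest.approx(30.0)
        assert FLAG_UNMARKED_ASSIGNED in d.flags

    def test_anticipated_from_first_version_on_or_after_start(self):
        # the pre-start figure (200) must be skipped in favour of the first
        # figure dated on/after the start date (100)
        h = make_history(
            make_version(version_date="2011-06-01", version_seq=0, enrollment=200,
                         start_date="2012-01-01"),
            make_version(version_date="2012-02-01", version_seq=1, enrollment=100,
                         start_date="2012-01-01"),
            make_version(version_date="2013-01-01", version_seq=2, enrollment=50,
                         enrollment_type=EnrollmentType.actual),
        )
        d = derive_degree_of_enrollment(h)
        assert d.anticipated_enrollment == 100
        assert d.degree_of_enrollment_pct == pytest.approx(50.0)

    def test_fallback_when_no_version_on_or_after_start(self):
        h = make_history(
            make_version(version_date="2011-06-01", version_seq=0, enrollment=200,
                         start_date="2012-01-01"),
            make_version(version_date="2011-08-01", version_seq=1, enrollment=10,
                         enrollment_type=EnrollmentType.actual),
        )
        d = derive_degree_of_enrollment(h)
        assert d.anticipated_enrollment == 200
        assert FLAG_NO_VERSION_ON_OR_AFTER_START in d.flags

    def test_actual_from_latest_actual_version_not_final(self):
        # a post-termination administrative edit without enrollment must not
        # erase the recorded actual figure
        h = make_history(
            make_version(version_seq=0, enrollment=100, start_date="2012-01-01"),
            make_version(version_date="2013-01-01", version_seq=1, enrollment=40,
                         enrollment_type=EnrollmentType.actual),
            make_version(version_date="2014-01-01", version_seq=2, enrollment=None),
        )
        d = derive_degree_of_enrollment(h)
        assert d.actual_enrollment == 40


class TestAggregateDegree:
    def test_cohort_totals_ratio(self):
        derived = [
            derive_degree_of_enrollment(terminated_history(20000, 10000, "NCT1")),
            derive_degree_of_enrollment(terminated_history(17379, 4723, "NCT2")),
        ]
        agg = aggregate_degree_of_enrollment(derived)
        assert agg.total_anticipated == 37379 and agg.total_actual == 14723
        assert agg.pct_rounded == 39

    def test_single_trial_full_attainment(self):
        agg = aggregate_degree_of_enrollment(
            [derive_degree_of_enrollment(terminated_history(50, 50))]
        )
        assert agg.pct == pytest.approx(100.0)

    def test_aggregate_is_sum_ratio_not_mean_of_ratios(self):
        trios = [(10, 5), (100, 10), (1000, 900)]
        derived = [
            derive_degree_of_enrollment(terminated_history(a, b, f"NCT{i}"))
            for i, (a, b) in enumerate(trios)
        ]
        agg = aggregate_degree_of_enrollment(derived)
        sum_ratio = 100 * sum(b for _, b in trios) / sum(a for a, _ in trios)
        mean_ratio = sum(100 * b / a for a, b in trios) / len(trios)
        assert agg.pct == pytest.approx(sum_ratio)
        assert abs(agg.pct - mean_ratio) > 1  # the two conventions differ here

    def test_all_missing_yields_no_result(self):
        h = make_history(make_version(version_seq=0, enrollment=None))
        agg = aggregate_degree_of_enrollment([derive_degree_of_enrollment(h)])
        assert agg.pct is None and agg.n_usable == 0


class TestTrialDays:
    def test_simple_date_arithmetic(self):
        h = make_history(
            make_version(version_seq=0, enrollment=10, start_date="2020-01-01"),
            make_version(version_date="2020-02-15", version_seq=1,
                         status=OverallStatus.terminated, enrollment=5,
                         enrollment_type=EnrollmentType.actual,
                         start_date="2020-01-01", pcd="2020-01-31"),
        )
        assert derive_trial_days(h).trial_days == 30

    def test_completed_only_history_flagged(self):
        h = make_history(
            make_version(version_seq=0, status=OverallStatus.completed, enrollment=10,
                         start_date="2020-01-01", pcd="2021-01-01")
        )
        d = derive_trial_days(h)
        assert d.trial_days is None
        assert FLAG_NO_TERMINATED_VERSION in d.flags

    def test_same_version_rule_ignores_later_dates(self):
        # the first terminated version lacks a primary completion date; a
        # later version carries one but must not be consulted
        h = make_history(
            make_version(version_seq=0, enrollment=10, start_date="2020-01-01"),
            make_version(version_date="2020-06-01", version_seq=1,
                         status=OverallStatus.terminated, enrollment=5,
                         enrollment_type=EnrollmentType.actual,
                         start_date="2020-01-01", pcd=None),
            make_version(version_date="2020-07-01", version_seq=2,
                         status=OverallStatus.terminated, enrollment=5,
                         enrollment_type=EnrollmentType.actual,
                         start_date="2020-01-01", pcd="2020-05-01"),
        )
        d = derive_trial_days(h)
        assert d.trial_days is None and d.stop_date is None

    def test_negative_difference_becomes_missing_plus_flag(self):
        h = make_history(
            make_version(version_seq=0, status=OverallStatus.terminated, enrollment=5,
                         enrollment_type=EnrollmentType.actual,
                         start_date="2020-06-01", pcd="2020-01-01")
        )
        d = derive_trial_days(h)
        assert d.trial_days is None
        assert FLAG_NEGATIVE_DURATION in d.flags


class TestSummaryResults:
    def test_final_version_flag_wins(self):
        h = make_history(
            make_version(version_seq=0, enrollment=10, has_summary_results=False),
            make_version(version_date="2013-01-01", version_seq=1, enrollment=10,
                         has_summary_results=True),
        )
        assert derive_summary_results(h).summary_results == "ctgov"

    def test_cross_registry_fallback(self):
        h = make_history(
            make_version(version_seq=0, enrollment=10, has_summary_results=False),
            euctr_available=True,
        )
        assert derive_summary_results(h).summary_results == "euctr_only"

    def test_flag_that_disappears_by_final_version_does_not_count(self):
        h = make_history(
            make_version(version_seq=0, enrollment=10, has_summary_results=True),
            make_version(version_date="2013-01-01", version_seq=1, enrollment=10,
                         has_summary_results=False),
        )
        assert derive_summary_results(h).summary_results == "none"


def test_derivation_is_permutation_invariant():
    """Derived variables depend on the ordered history, never on the order
    rows arrived in (the container sorts)."""
    versions = [
        make_version(version_seq=0, enrollment=100, start_date="2012-01-01",
                     pcd="2014-01-01"),
        make_version(version_date="2012-09-01", version_seq=1, enrollment=120),
        make_version(version_date="2013-06-01", version_seq=2,
                     status=OverallStatus.terminated, enrollment=44,
                     enrollment_type=EnrollmentType.actual, start_date="2012-01-01",
                     pcd="2013-05-01", has_summary_results=True),
    ]
    reference = derive_variables(make_history(*versions))
    shuffled = TrialHistory(
        trial_id=versions[0].trial_id, versions=(versions[2], versions[0], versions[1])
    )
    assert derive_variables(shuffled) == reference
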