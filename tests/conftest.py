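import datetime as dt

import pytest

from termtrials.registry import (
    EnrollmentType,
    OverallStatus,
    TrialHistory,
    TrialVersion,
)
from termtrials.synthetic import (
    CohortConfig,
    generate_cascade_fixture,
    generate_cohort,
    generate_mesh_fixture,
)


def make_version(
    trial_id="NCT00000001",
    version_date="2012-01-01",
    version_seq=0,
    status=OverallStatus.recruiting,
    enrollment=None,
    enrollment_type=None,
    start_date=None,
    pcd=None,
    why_stopped="",
    has_summary_results=False,
):
    """Terse TrialVersion builder for handcrafted histories."""
    if enrollment_type is None:
        enrollment_type = (
            EnrollmentType.missing if enrollment is None else EnrollmentType.anticipated
        )
    return TrialVersion(
        trial_id=trial_id,
        version_date=dt.date.fromisoformat(version_date),
        version_seq=version_seq,
        overall_status=status,
        enrollment_count=enrollment,
        enrollment_type=enrollment_type,
        start_date=None if start_date is None else dt.date.fromisoformat(start_date),
        primary_completion_date=None if pcd is None else dt.date.fromisoformat(pcd),
        why_stopped=why_stopped,
        has_summary_results=has_summary_results,
    )


def make_history(*versions, euctr_available=False, euctr_tabular=False):
    return TrialHistory(
        trial_id=versions[0].trial_id,
        versions=tuple(versions),
        euctr_results_available=euctr_available,
        euctr_results_tabular=euctr_tabular,
    )


@pytest.fixture(scope="session")
def mesh_tree():
    return generate_mesh_fixture()


@pytest.fixture(scope="session")
def cascade_fixture():
    return generate_cascade_fixture()


@pytest.fixture(scope="session")
def small_cohort():
    return generate_cohort(CohortConfig(seed=7, n_trials=120))
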