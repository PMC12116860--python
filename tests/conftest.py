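import pandas as pd
import pytest

from asep.core import asep_by_participant, results_frame
from asep.synthetic import generate_cohort, worked_example_tables


@pytest.fixture(scope="session")
def cohort():
    """Default synthetic cohort, shared read-only across the suite."""
    return generate_cohort(seed=1)


@pytest.fixture(scope="session")
def cohort_asep(cohort):
    """(daily frame with diet_category, AsepResult list) for the cohort."""
    daily, results = asep_by_participant(
        cohort.records, cohort.food_items, cohort.participants
    )
    return daily, results


@pytest.fixture(scope="session")
def cohort_period_asep(cohort_asep) -> pd.Series:
    _, results = cohort_asep
    return results_frame(results).set_index("participant_id")["period_asep"]


@pytest.fixture()
def example():
    return worked_example_tables()
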