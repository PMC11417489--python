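import numpy as np
import pandas as pd
import pytest

from wearadhere import CohortConfig, generate_cohort
from wearadhere.day_accounting import build_day_records
from wearadhere.adherence import summarize_cohort
from wearadhere.synthetic import profiles_to_frame


@pytest.fixture(scope="session")
def small_config():
    return CohortConfig(n_participants=60, seed=7)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    """(profiles, schedules, day_wear) for a 60-participant cohort."""
    return generate_cohort(small_config)


@pytest.fixture(scope="session")
def small_day_records(small_config, small_cohort):
    profiles, schedules, day_wear = small_cohort
    return build_day_records(day_wear, schedules, protocol_days=small_config.protocol_days)


@pytest.fixture(scope="session")
def small_summaries(small_config, small_day_records):
    return summarize_cohort(small_day_records, protocol_days=small_config.protocol_days)


@pytest.fixture(scope="session")
def small_profiles_frame(small_cohort):
    return profiles_to_frame(small_cohort[0])
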