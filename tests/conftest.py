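import numpy as np
import pytest
from hypothesis import settings

import isdi

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def toy_map():
    return isdi.load_toy_map()


@pytest.fixture(scope="session")
def small_cohort():
    """A modest cohort with default calibration, 5% MCAR missingness."""
    return isdi.generate_cohort(isdi.CohortSpec(n_participants=2500, seed=7))


@pytest.fixture(scope="session")
def encoded_small(small_cohort):
    return isdi.encode_responses(small_cohort.survey_raw, isdi.CodingTable())


@pytest.fixture(scope="session")
def completed_small(encoded_small):
    best, cset = isdi.impute_and_select(
        encoded_small, isdi.ImputationConfig(m=2, max_iterations=3, seed=11)
    )
    return best, cset


@pytest.fixture(scope="session")
def complete_cohort_20k():
    """Calibrated cohort at study-test scale, generated without missingness
    (used for index truth-recovery and correlation-structure checks)."""
    spec = isdi.CohortSpec(n_participants=20_000, seed=29, missing_rate=0.0)
    cohort = isdi.generate_cohort(spec)
    table = isdi.encode_responses(cohort.survey_raw, isdi.CodingTable())
    return cohort, table


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
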