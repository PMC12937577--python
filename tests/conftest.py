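import pytest

import jiacea as j


@pytest.fixture(scope="session")
def value_set():
    return j.default_value_set()


@pytest.fixture(scope="session")
def schedule():
    return j.default_schedule()


@pytest.fixture(scope="session")
def life_table():
    return j.default_life_table()


@pytest.fixture(scope="session")
def big_params():
    """Default survey-calibrated generator at a Monte-Carlo-friendly size."""
    return j.CohortParams(n_total=10_000, seed=7)


@pytest.fixture(scope="session")
def big_cohort(big_params):
    return j.generate_cohort(big_params)


@pytest.fixture(scope="session")
def small_cohort():
    return j.generate_cohort(j.CohortParams(n_total=400, seed=3))
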