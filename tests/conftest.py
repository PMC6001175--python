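import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from hbresponse.cohort import concat_cohorts, design_frame, load_fixture_table1
from hbresponse.pipeline import study_split_scheme
from hbresponse.simulate import (
    early_cohort_config,
    generate_cohort,
    new_cohort_config,
)


@pytest.fixture(scope="session")
def table1():
    return load_fixture_table1()


@pytest.fixture(scope="session")
def study_pair():
    """One (early, new) synthetic cohort pair at the study conditions."""
    early = generate_cohort(early_cohort_config(seed=101))
    new = generate_cohort(new_cohort_config(seed=202))
    return early, new


@pytest.fixture(scope="session")
def study_frame(study_pair):
    early, new = study_pair
    return design_frame(concat_cohorts(early, new))


@pytest.fixture(scope="session")
def study_scheme(study_pair):
    early, new = study_pair
    return study_split_scheme(new, early)


@pytest.fixture()
def rng():
    return np.random.default_rng(20180614)
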