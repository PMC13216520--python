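import pytest

from hallmark_timing.simulate import CohortConfig, generate_cohort, synthetic_catalog


@pytest.fixture(scope="session")
def catalog():
    return synthetic_catalog()


@pytest.fixture(scope="session")
def small_cohort():
    """A fast cohort with the default planted structure at reduced size."""
    return generate_cohort(CohortConfig(n_egi=60, n_lgi=60, seed=7))


@pytest.fixture(scope="session")
def default_cohort():
    """The default study-condition cohort: 200 patients per group."""
    return generate_cohort(CohortConfig(seed=123))


@pytest.fixture(scope="session")
def default_fit(default_cohort):
    from hallmark_timing import HallmarkTimingModel

    return HallmarkTimingModel.from_cohort(default_cohort, R=500).fit(seed=123)
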