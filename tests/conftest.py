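import pytest

from nutriprofile import CohortConfig, generate_cohort
from nutriprofile.cohort import liking_columns


@pytest.fixture(scope="session")
def small_cohort():
    """1,500 participants with complete data; enough signal for the
    mixture and tree tests without slowing the suite."""
    return generate_cohort(CohortConfig(n_participants=1500, seed=7,
                                        missing_rate=0.0))


@pytest.fixture(scope="session")
def missing_cohort():
    """800 participants with 5% values missing at random."""
    return generate_cohort(CohortConfig(n_participants=800, seed=11,
                                        missing_rate=0.05))


@pytest.fixture(scope="session")
def liking_matrix(small_cohort):
    return small_cohort.data[liking_columns()]
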