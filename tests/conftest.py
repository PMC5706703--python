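import numpy as np
import pytest

from candycatch.cohort import CohortSpec, GroupSpec, simulate_cohort
from candycatch.estimation import fit_cohort_slopes
from candycatch.task import TaskDesign, DEFAULT_DESIGN


@pytest.fixture(scope="session")
def design():
    return DEFAULT_DESIGN


@pytest.fixture(scope="session")
def small_design():
    """Cut-down schedule (2 blocks x 30 trials) for fast pipeline tests."""
    return TaskDesign(n_blocks=2, trials_per_block=30)


@pytest.fixture(scope="session")
def cohort(design):
    """Study-sized default cohort (9 CP + 9 TD, 480 trials each), seed 7."""
    return simulate_cohort(seed=7)


@pytest.fixture(scope="session")
def cohort_slopes(cohort, design):
    return fit_cohort_slopes(cohort, design, n_boot=200, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
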