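import warnings

import pytest
from hypothesis import settings

from incentives_cea.costing import UnitCostTable, VoucherSchedule
from incentives_cea.synthetic_cohort import CohortSpec, generate_cohort, generate_trial_table

settings.register_profile("default", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("default")

warnings.filterwarnings("ignore", category=RuntimeWarning)
warnings.filterwarnings("ignore", message=".*convergence.*")


@pytest.fixture(scope="session")
def schedule():
    return VoucherSchedule()


@pytest.fixture(scope="session")
def unit_costs():
    return UnitCostTable()


@pytest.fixture(scope="session")
def trial_spec():
    return CohortSpec(seed=11)


@pytest.fixture(scope="session")
def full_cohort(trial_spec):
    """Trial-sized cohort before missingness (full information)."""
    return generate_cohort(trial_spec)


@pytest.fixture(scope="session")
def masked_cohort(trial_spec):
    """Trial-sized cohort with the configured MAR missingness applied."""
    return generate_trial_table(trial_spec)


@pytest.fixture(scope="session")
def big_cohort():
    """Ten-times-scale cohort for checks on calibrated marginals."""
    return generate_cohort(CohortSpec(n_incentives=4710, n_control=4700, seed=5))
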