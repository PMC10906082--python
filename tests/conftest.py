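import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from seqcea.cohort import LifeTable
from seqcea.synthetic import calibrate_to_base_case, make_base_case_config

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

#: single master seed for every stochastic fixture in the suite
MASTER_SEED = 1


@pytest.fixture(scope="session")
def base_config() -> dict:
    return make_base_case_config()


@pytest.fixture(scope="session")
def calibrated_config() -> dict:
    """Base-case configuration calibrated to the published totals.

    Session-scoped: calibration is deterministic, so computing it once is
    safe and keeps the suite fast.
    """
    return calibrate_to_base_case(make_base_case_config())


@pytest.fixture()
def zero_life_table() -> LifeTable:
    """No background mortality: isolates disease-driven transitions."""
    return LifeTable(np.arange(40, 101), np.zeros(61))
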