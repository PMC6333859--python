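import numpy as np
import pytest

from epikinet import PlasmaInput, make_frame_schedule
from epikinet.synthetic_cohort import DEFAULT_FRAME_GROUPS, simulate_input_function


@pytest.fixture(scope="session")
def schedule():
    """The default 39-frame, 60-minute dynamic protocol."""
    return make_frame_schedule(DEFAULT_FRAME_GROUPS)


@pytest.fixture(scope="session")
def bolus_input(schedule):
    """Densely sampled Feng bolus covering the default schedule."""
    return simulate_input_function(t_end_min=schedule.total_duration / 60.0 + 1.0)


@pytest.fixture(scope="session")
def constant_input():
    """Constant-infusion input (Cp = 10 from t = 0), for closed-form checks."""
    return PlasmaInput(times_min=np.array([0.0, 120.0]), values=np.array([10.0, 10.0]))
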