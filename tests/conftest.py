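import numpy as np
import pytest

import cvepsim as cv
from cvepsim.study import calibrate_subject, default_timelines


@pytest.fixture(scope="session")
def base_code():
    return cv.generate_m_sequence()


@pytest.fixture(scope="session")
def timelines():
    """Per-class two-cycle 600 Hz timelines of the default codes."""
    return default_timelines()


@pytest.fixture(scope="session")
def subject():
    """A mid-focus synthetic participant at the default operating point."""
    return cv.sample_subject(101, focus_target=0.7)


@pytest.fixture(scope="session")
def trained(subject):
    """A calibrated 16-channel model for the session subject."""
    return calibrate_subject(subject, rng=202)


@pytest.fixture(scope="session")
def noiseless_subject():
    """Impulse-kernel, zero-latency subject whose epochs are exactly code-locked."""
    kernel = np.zeros(8)
    kernel[0] = 1.0
    return cv.sample_subject(
        7, focus_target=0.7, kernel=kernel, latency_range=(0.0, 0.0)
    )


@pytest.fixture(scope="session")
def fixture_table():
    return cv.packaged_study_table()
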