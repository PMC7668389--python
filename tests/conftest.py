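import numpy as np
import pytest

from ppgsynth import PulseParams, PulseSpec, pulse_waveform

#: Regular-template mean parameters (the default reference-beat morphology).
REGULAR_MEANS = PulseParams(
    a1=0.997, a2=0.225, b1=0.641, b2=0.937, theta1=-1.471, theta2=1.019
)

#: Compensation-template first-beat mean parameters.
COMPENSATION_FIRST_MEANS = PulseParams(
    a1=0.829, a2=0.420, b1=0.732, b2=1.219, theta1=-1.008, theta2=0.450
)


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


@pytest.fixture
def regular_means():
    return REGULAR_MEANS


@pytest.fixture
def regular_pulse_250():
    """One clean beat synthesized from the regular-template means
    (T = 1 s, fs = 250 Hz)."""
    return pulse_waveform(REGULAR_MEANS, PulseSpec(duration_T=1.0, fs=250.0))
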