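import numpy as np
import pytest

from vibropsych.psychofit import BinomialData, PsychometricParams, predict
from vibropsych.stimgen import PulseSpec, TrainSpec, make_train


@pytest.fixture(scope="session")
def reference_train():
    """The reference stimulus: 90 Hz train of 170 Hz pulses, 500 ms, 40 µm."""
    return make_train(TrainSpec())


@pytest.fixture(scope="session")
def shape_family():
    """Pulse-shape stimulus family: waveform frequency 170..240 Hz at rate 90."""
    return [TrainSpec(pulse=PulseSpec(float(f), 40.0)) for f in range(170, 245, 5)]


@pytest.fixture(scope="session")
def rate_family():
    """Pulse-rate stimulus family: rate 90..135 Hz with the reference pulse."""
    return [TrainSpec(pulse_rate_hz=float(r)) for r in range(90, 140, 5)]


@pytest.fixture
def shape_levels():
    return np.arange(175.0, 245.0, 5.0)


def simulate_binomial(params: PsychometricParams, levels, n_per_level, rng) -> BinomialData:
    """Draw binomial counts from a psychometric ground truth (test oracle)."""
    levels = np.asarray(levels, dtype=float)
    p = np.asarray(predict(params, levels))
    n = np.full(levels.size, n_per_level)
    return BinomialData(levels, n, rng.binomial(n, p))
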