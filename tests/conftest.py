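import numpy as np
import pytest

from biopot import preprocess as pp
from biopot import simulate as sim


@pytest.fixture(scope="session")
def ecg_60beats():
    """Clean 60-beat ECG at constant RR 1000 ms, 240 Hz."""
    return sim.gen_ecg([1000.0] * 60, fs=240.0, seed=11)


@pytest.fixture(scope="session")
def ecg_60beats_noisy():
    """Same train at 20 dB SNR (R amplitude 1 mV, noise 0.1 mV RMS)."""
    return sim.gen_ecg([1000.0] * 60, fs=240.0, seed=11, noise_rms_mv=0.1)


@pytest.fixture(scope="session")
def emg_three_bursts():
    """Three 5 s-on / 5 s-off contraction cycles at 960 Hz."""
    return sim.gen_emg([(5.0, 10.0), (15.0, 20.0), (25.0, 30.0)], fs=960.0,
                       duration_s=35.0, seed=21)


@pytest.fixture(scope="session")
def emg_envelope_three(emg_three_bursts):
    return pp.emg_envelope(emg_three_bursts)
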