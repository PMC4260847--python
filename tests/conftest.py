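import sys
import warnings
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from plmad.model import Hypnogram, SignalTrace
from plmad.synth import SynthSpec, Train, generate


@pytest.fixture(autouse=True)
def _quiet_short_recording_warning():
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="recording spans")
        yield


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def flat_hypnogram():
    """Two hours of stage-2 sleep."""
    return Hypnogram(stages=["S2"] * 240, epoch_len_s=30.0)


def make_trace(samples, fs=100.0, label="leg"):
    return SignalTrace(np.asarray(samples, dtype=float), fs, label)


@pytest.fixture(scope="session")
def train_fixture():
    """30-minute recording with one planted periodic train of 10 LMs."""
    spec = SynthSpec(
        duration_h=0.5,
        fs_hz=200.0,
        seed=7,
        trains=[Train(start_s=120.0, count=10, imi_s=30.0, amplitude_uv=25.0)],
        ecg_leak=0.1,
    )
    return spec, generate(spec)


def as_roles(recording, with_ecg=True):
    """Map the generator's EDF labels onto the detector's channel roles."""
    from plmad.model import Recording

    traces = {"leg_left": recording["LAT"], "leg_right": recording["RAT"]}
    if with_ecg and "ECG" in recording:
        traces["ecg"] = recording["ECG"]
    return Recording(traces=traces, duration_s=recording.duration_s, meta=recording.meta)
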