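import numpy as np
import pytest

from fmsf.preprocess import Segment
from fmsf.synthetic import TraceSpec, simulate_trace

FS = 25.0


def make_segment(values, start_s=0.0, fs=FS, label="rest"):
    values = np.asarray(values, dtype=float)
    return Segment(label=label, start_s=start_s,
                   end_s=start_s + len(values) / fs,
                   values=values, sampling_rate=fs)


def tone_segment(amplitude, freq_hz, duration_s=150.0, fs=FS, baseline=1.0,
                 phase=0.0, label="rest"):
    """A sinusoid on a flat baseline, as a ready-made analysis segment."""
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    values = baseline + amplitude * np.sin(2 * np.pi * freq_hz * t + phase)
    return make_segment(values, fs=fs, label=label)


@pytest.fixture(scope="session")
def full_porh_trace():
    """Default full-protocol simulated trace with its ground truth."""
    return simulate_trace(TraceSpec.full_porh(seed=42))


@pytest.fixture(scope="session")
def rest_only_trace():
    return simulate_trace(TraceSpec(seed=7))
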