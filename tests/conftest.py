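import numpy as np
import pytest

from bipr.trace import PupilTrace


def make_trace(values, fs=1000.0, t0=0.0):
    values = np.asarray(values, dtype=float)
    t = t0 + np.arange(values.size) * (1000.0 / fs)
    return PupilTrace(t_ms=t, pupil=values, sampling_rate=fs)


@pytest.fixture
def constant_trace():
    """10 s of constant 800 a.u. at 1 kHz."""
    return make_trace(np.full(10_000, 800.0))


def insert_zero_span(trace, onset_ms, duration_ms):
    x = trace.pupil.copy()
    step = trace.dt_ms
    i0 = int(round(onset_ms / step))
    i1 = i0 + int(round(duration_ms / step))
    x[i0:i1] = 0.0
    return trace.copy(pupil=x)
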