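import numpy as np
import pytest

from sgnmech.core_io import SinusoidStimulus, SpikeTrain, Trace


@pytest.fixture
def voltage_trace():
    """Flat -60 mV trace with one triangular excursion peaking +20 mV at 5 ms."""
    dt = 0.05
    v = np.full(400, -60.0)
    peak = int(5.0 / dt)
    half = int(0.5 / dt)
    for j in range(-half, half + 1):
        v[peak + j] = 20.0 * (1 - abs(j) / half) - 60.0 * (abs(j) / half)
    return Trace(dt=dt, samples=v, kind="voltage")


@pytest.fixture
def sinusoid_50hz():
    return SinusoidStimulus("displacement", frequency=50.0, amplitude=0.2,
                            onset=0.0, duration=1000.0)


def make_train(times, duration, stim=None):
    return SpikeTrain(times=np.asarray(times, float),
                      record_duration=duration, stimulus=stim)
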