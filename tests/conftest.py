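import numpy as np
import pytest

from apcsim import LarvaEvent, NoiseModel, synthesize_trace


@pytest.fixture
def noise6():
    return NoiseModel(noise_std=6.0)


@pytest.fixture
def quiet():
    return NoiseModel(noise_std=0.0)


def pulse_trace(times, amplitude=100.0, noise_std=6.0, duration=None,
                velocity=980.0, seed=0, sampling_rate=10.0):
    """Trace with rectangular larva pulses at the given arrival times."""
    events = [LarvaEvent(t, amplitude) for t in times]
    if duration is None:
        duration = (max(times) + 0.05) if times else 0.1
    return synthesize_trace(events, NoiseModel(noise_std=noise_std),
                            velocity=velocity, duration=duration,
                            seed=seed, sampling_rate=sampling_rate)


def random_trace(rng, n=600, lag_quiet=50):
    """Adversarial random series for detector equivalence testing: noise,
    a slow random-walk baseline and a handful of random square pulses."""
    from apcsim.stream_sim import SensorTrace
    base = 500.0 + np.cumsum(rng.normal(0, 0.05, n))
    x = base + rng.normal(0, rng.uniform(2, 10), n)
    for _ in range(rng.integers(0, 6)):
        start = rng.integers(lag_quiet, n - 5)
        width = rng.integers(2, 40)
        x[start:start + width] -= rng.uniform(10, 150)
    np.maximum(x, 0.0, out=x)
    return SensorTrace(sampling_rate=10.0, intensities=x)
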