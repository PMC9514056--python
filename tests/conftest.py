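import numpy as np
import pytest

from hrvbf.core import RPeakSeries
from hrvbf.synthetic import CardiorespSimParams, simulate_beats


@pytest.fixture(scope="session")
def constant_beats():
    """Metronomic 800-ms series, 120 s (no RSA, no jitter)."""
    params = CardiorespSimParams(duration=120, base_period=800,
                                 rsa_half_amplitude=0, resp_freq=0.1, seed=1)
    beats, resp, truth = simulate_beats(params)
    return beats, resp, truth


@pytest.fixture(scope="session")
def rsa_beats():
    """5-min series with 40-ms RSA at 0.1 Hz and 10-ms jitter."""
    params = CardiorespSimParams(duration=300, base_period=800,
                                 rsa_half_amplitude=40, resp_freq=0.1,
                                 period_jitter_sd=10, seed=7)
    return simulate_beats(params)


def nn_constructed_beats(freq, half_amp=30.0, base=1000.0, duration=300.0):
    """Beat series whose NN values are exact samples of a sinusoid."""
    t = [0.0]
    while t[-1] < duration:
        t.append(t[-1] + (base + half_amp * np.sin(2 * np.pi * freq * t[-1])) / 1000.0)
    return RPeakSeries(np.asarray(t))
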