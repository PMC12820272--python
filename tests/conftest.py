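import numpy as np
import pytest

from ripplefloor import SignalTrace, generate_colored_noise


@pytest.fixture(scope="session")
def white_trace():
    """600 s of preprocessed white noise (chi = 0) at 1000 Hz."""
    return generate_colored_noise(0.0, 600.0, 1000.0, seed=101)


@pytest.fixture(scope="session")
def brown_trace():
    """600 s of preprocessed chi = -2 colored noise at 1000 Hz."""
    return generate_colored_noise(-2.0, 600.0, 1000.0, seed=102)


@pytest.fixture()
def rng():
    return np.random.default_rng(7)


@pytest.fixture()
def short_sine():
    """60 s pure 10 Hz sinusoid with weak white noise."""
    t = np.arange(60_000) / 1000.0
    g = np.random.default_rng(3)
    return SignalTrace(np.sin(2 * np.pi * 10 * t) + 0.01 * g.standard_normal(t.size), 1000.0)
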