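import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from eptools.signals import (
    DEFAULT_GRID,
    STANDARD_SPECS,
    SamplingGrid,
    generate_composite,
    generate_sine,
)


@pytest.fixture(scope="session")
def grid():
    return DEFAULT_GRID


@pytest.fixture(scope="session")
def standard_waves(grid):
    """The three 10 µV validation sinusoids keyed by frequency in Hz."""
    return {int(s.frequency_hz): generate_sine(s, grid) for s in STANDARD_SPECS}


@pytest.fixture(scope="session")
def composite_wave(grid):
    return generate_composite(list(STANDARD_SPECS), grid)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240265)


def random_smooth_wave(rng, n_samples=2000, n_harmonics=6, duration_ms=10.0):
    """A random band-limited waveform (sum of low harmonics) for oracle tests."""
    grid = SamplingGrid(duration_ms=duration_ms, n_samples=n_samples)
    t = grid.times()
    y = np.zeros_like(t)
    for _ in range(n_harmonics):
        f = rng.uniform(100.0, 900.0)  # Hz
        a = rng.uniform(0.5, 10.0)
        phi = rng.uniform(0, 2 * np.pi)
        y += a * np.sin(2 * np.pi * f * t / 1000.0 + phi)
    from eptools.signals import Waveform

    return Waveform(times=t, amplitudes=y, label="random")
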