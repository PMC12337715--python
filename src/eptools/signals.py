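"""Synthetic sinusoid generation and analytic landmark expectations.

The validation fixtures of this toolkit are pure sinusoids

    y(t) = A * sin(2*pi*f*t)

sampled on a uniform grid: by default 3072 points spanning a 10 ms sweep
(the short window of a brainstem-response recording), with test frequencies
of 0.5, 1 and 2 kHz at +/-10 µV, plus their pointwise sum as a composite
wave. Because the first peak, trough and zero-crossing of a zero-phase
sinusoid sit at 1/(4f), 3/(4f) and 1/(2f), every downstream measure
(latency, amplitude, P1N1 area, slope) has a closed form; those analytic
expectations are returned as a :class:`LandmarkSet` and serve as ground
truth for the marking and measurement machinery.

Units follow clinical convention throughout: time in milliseconds,
amplitude in microvolts, frequency in hertz.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ParameterError

__all__ = [
    "SineSpec",
    "SamplingGrid",
    "Waveform",
    "LandmarkSet",
    "generate_sine",
    "generate_composite",
    "analytic_landmarks",
    "standard_fixtures",
    "DEFAULT_GRID",
    "STANDARD_SPECS",
]

#: Relative tolerance for the uniform-spacing invariant of a Waveform.
_SPACING_RTOL = 1e-9


@dataclass(frozen=True)
class SineSpec:
    """A zero-phase sinusoid: frequency in Hz, peak amplitude in µV."""

    frequency_hz: float
    amplitude_uv: float

    def __post_init__(self) -> None:
        if not self.frequency_hz > 0:
            raise ParameterError(f"frequency must be > 0 Hz, got {self.frequency_hz}")
        if not self.amplitude_uv > 0:
            raise ParameterError(f"amplitude must be > 0 µV, got {self.amplitude_uv}")


@dataclass(frozen=True)
class SamplingGrid:
    """Uniform time grid for waveform synthesis.

    ``endpoint_mode``:

    * ``"half-open"`` (default): t_k = start + k*duration/n, k = 0..n-1 —
      the endpoint is excluded, spacing is duration/n, and an integer
      number of cycles fits the window exactly (so FFT bins land on the
      stimulus frequencies).
    * ``"inclusive"``: t_k = start + k*duration/(n-1) — both endpoints
      sampled, spacing duration/(n-1).
    """

    start_ms: float = 0.0
    duration_ms: float = 10.0
    n_samples: int = 3072
    endpoint_mode: str = "half-open"

    def __post_init__(self) -> None:
        if self.n_samples < 2:
            raise ParameterError(f"n_samples must be >= 2, got {self.n_samples}")
        if not self.duration_ms > 0:
            raise ParameterError(f"duration must be > 0 ms, got {self.duration_ms}")
        if self.endpoint_mode not in ("half-open", "inclusive"):
            raise ParameterError(f"unknown endpoint_mode {self.endpoint_mode!r}")

    @property
    def dt_ms(self) -> float:
        if self.endpoint_mode == "half-open":
            return self.duration_ms / self.n_samples
        return self.duration_ms / (self.n_samples - 1)

    def times(self) -> np.ndarray:
        """Sample times in ms."""
        return self.start_ms + np.arange(self.n_samples) * self.dt_ms


@dataclass
class Waveform:
    """A sampled trace: strictly increasing, uniformly spaced times (ms)
    and matching amplitudes (µV)."""

    times: np.ndarray
    amplitudes: np.ndarray
    label: str = ""
    channel: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        if self.times.ndim != 1 or self.amplitudes.ndim != 1:
            raise ParameterError("times and amplitudes must be 1-D")
        if len(self.times) != len(self.amplitudes):
            raise ParameterError(
                f"length mismatch: {len(self.times)} times vs "
                f"{len(self.amplitudes)} amplitudes"
            )
        if len(self.times) < 2:
            raise ParameterError("a waveform needs at least 2 samples")
        steps = np.diff(self.times)
        if np.any(steps <= 0):
            raise ParameterError("times must be strictly increasing")
        if not np.allclose(steps, steps[0], rtol=_SPACING_RTOL, atol=0.0):
            raise ParameterError("sample spacing must be uniform")

    @property
    def n_samples(self) -> int:
        return len(self.times)

    @property
    def dt_ms(self) -> float:
        return float(self.times[1] - self.times[0])

    @property
    def span_ms(self) -> tuple[float, float]:
        return float(self.times[0]), float(self.times[-1])

    @property
    def sampling_rate_hz(self) -> float:
        return 1000.0 / self.dt_ms

    def __add__(self, other: "Waveform") -> "Waveform":
        if not np.array_equal(self.times, other.times):
            raise ParameterError("waveforms must share a time axis to be summed")
        return Waveform(
            times=self.times.copy(),
            amplitudes=self.amplitudes + other.amplitudes,
            label=f"{self.label}+{other.label}".strip("+"),
            channel=self.channel,
        )


@dataclass(frozen=True)
class LandmarkSet:
    """Closed-form first-peak/first-trough landmarks of a pure sinusoid.

    Areas are over the peak-to-trough half period: ``abs_area`` is the
    integral of |y| (µV·ms), ``two_triangle_area`` the two-right-triangle
    approximation through the zero-crossing. ``slope`` is the
    peak-to-trough amplitude over the peak-to-trough interval (µV/ms).
    """

    t_peak_ms: float
    t_trough_ms: float
    t_zero_ms: float
    peak_amplitude_uv: float
    trough_amplitude_uv: float
    peak_to_trough_amplitude_uv: float = field(init=False)
    abs_area_uv_ms: float = 0.0
    two_triangle_area_uv_ms: float = 0.0
    slope_uv_per_ms: float = 0.0

    def __post_init__(self) -> None:
        if not self.t_peak_ms < self.t_zero_ms < self.t_trough_ms:
            raise ParameterError("landmarks must satisfy t_peak < t_zero < t_trough")
        object.__setattr__(
            self,
            "peak_to_trough_amplitude_uv",
            self.peak_amplitude_uv - self.trough_amplitude_uv,
        )


#: Default sweep grid: 3072 samples over 10 ms, endpoint excluded.
DEFAULT_GRID = SamplingGrid()

#: The standard validation sinusoids: 0.5/1/2 kHz at +/-10 µV.
STANDARD_SPECS = (
    SineSpec(500.0, 10.0),
    SineSpec(1000.0, 10.0),
    SineSpec(2000.0, 10.0),
)


def generate_sine(spec: SineSpec, grid: SamplingGrid = DEFAULT_GRID) -> Waveform:
    """Sample ``A*sin(2*pi*f*t)`` on the grid.

    The returned waveform is labelled with the frequency (e.g. ``"500Hz"``).
    """
    t_ms = grid.times()
    y = spec.amplitude_uv * np.sin(2.0 * np.pi * spec.frequency_hz * t_ms / 1000.0)
    label = (
        f"{spec.frequency_hz:g}Hz"
        if float(spec.frequency_hz).is_integer()
        else f"{spec.frequency_hz}Hz"
    )
    return Waveform(times=t_ms, amplitudes=y, label=label, channel=label)


def generate_composite(
    specs: list[SineSpec] | tuple[SineSpec, ...],
    grid: SamplingGrid = DEFAULT_GRID,
    label: str = "sum",
) -> Waveform:
    """Pointwise sum of sinusoids sharing one grid (the composite wave)."""
    if len(specs) == 0:
        raise ParameterError("generate_composite needs at least one SineSpec")
    t_ms = grid.times()
    y = np.zeros_like(t_ms)
    for spec in specs:
        y = y + spec.amplitude_uv * np.sin(
            2.0 * np.pi * spec.frequency_hz * t_ms / 1000.0
        )
    return Waveform(times=t_ms, amplitudes=y, label=label, channel=label)


def analytic_landmarks(spec: SineSpec) -> LandmarkSet:
    """Closed-form landmark expectations for a zero-phase sinusoid.

    First peak at 1/(4f), trough at 3/(4f), zero-crossing at 1/(2f);
    integral of |y| over [t_peak, t_trough] is A/(pi*f); the two-triangle
    approximation is A/(4f) per triangle pair (exactly pi/4 of the
    integral); slope is 2A / (half period) = 4*A*f.
    """
    f = spec.frequency_hz
    a = spec.amplitude_uv
    t_peak = 1000.0 / (4.0 * f)  # ms
    t_trough = 3000.0 / (4.0 * f)
    t_zero = 1000.0 / (2.0 * f)
    abs_area = 1000.0 * a / (math.pi * f)  # µV·ms
    two_triangle = (t_zero - t_peak) * a / 2.0 + (t_trough - t_zero) * a / 2.0
    slope = 2.0 * a / (t_trough - t_peak)
    return LandmarkSet(
        t_peak_ms=t_peak,
        t_trough_ms=t_trough,
        t_zero_ms=t_zero,
        peak_amplitude_uv=a,
        trough_amplitude_uv=-a,
        abs_area_uv_ms=abs_area,
        two_triangle_area_uv_ms=two_triangle,
        slope_uv_per_ms=slope,
    )


def standard_fixtures(
    grid: SamplingGrid = DEFAULT_GRID,
) -> tuple[list[Waveform], Waveform]:
    """The three standard sinusoids plus their sum on one grid."""
    singles = [generate_sine(s, grid) for s in STANDARD_SPECS]
    composite = generate_composite(list(STANDARD_SPECS), grid)
    return singles, composite
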