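"""Single-sided amplitude spectra and spectral-peak marking.

The spectrum of a rectangular-windowed (untapered) segment is scaled so
that a sinusoid of peak amplitude A µV whose frequency falls exactly on a
bin shows amplitude A at that bin — i.e. half the peak-to-peak swing,
which is the reading a clinician expects when inspecting the frequency
content of a steady-state or frequency-following response:

    amplitude[k] = 2*|Y_k| / N   for 0 < k < N/2
    amplitude[k] =   |Y_k| / N   at DC and (even N) Nyquist

where Y is the DFT of the N time samples. Resolution is fs/N; with the
default 3072-sample, 10 ms sweep the bins sit every 100 Hz, so the 0.5/1/2
kHz test tones land exactly on bins 5, 10 and 20.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import DetectionError, ParameterError, RangeError
from .signals import Waveform

__all__ = [
    "Spectrum",
    "SpectralPeak",
    "amplitude_spectrum",
    "auto_mark_spectral_peaks",
    "mark_spectral_peak",
]


@dataclass
class Spectrum:
    """Single-sided amplitude spectrum: frequencies (Hz) from 0, µV amplitudes."""

    frequencies_hz: np.ndarray
    amplitudes_uv: np.ndarray
    resolution_hz: float
    window_ms: tuple[float, float]
    taper: str = "rectangular"

    def __post_init__(self) -> None:
        self.frequencies_hz = np.asarray(self.frequencies_hz, dtype=float)
        self.amplitudes_uv = np.asarray(self.amplitudes_uv, dtype=float)
        if len(self.frequencies_hz) != len(self.amplitudes_uv):
            raise ParameterError("frequency and amplitude arrays differ in length")

    @property
    def n_bins(self) -> int:
        return len(self.frequencies_hz)


@dataclass(frozen=True)
class SpectralPeak:
    """A marked spectral line: exact bin frequency and its amplitude."""

    frequency_hz: float
    amplitude_uv: float
    bin_index: int
    source: str = "auto"


def amplitude_spectrum(
    waveform: Waveform,
    interval_ms: tuple[float, float] | None = None,
    zero_pad_factor: int = 1,
) -> Spectrum:
    """Single-sided amplitude spectrum of a waveform (or a time interval of it).

    ``interval_ms`` selects whole samples (floor for the start, ceil for
    the end, which is excluded — half-open). ``zero_pad_factor`` > 1 appends zeros to refine the displayed
    bin spacing; amplitudes keep the 2/N scaling of the *data* length so a
    bin-centred sinusoid still reads A µV.
    """
    t = waveform.times
    y = waveform.amplitudes
    if interval_ms is not None:
        lo, hi = interval_ms
        if not lo < hi:
            raise ParameterError("interval must be ordered")
        if lo < t[0] - 1e-12 or hi > t[-1] + 1e-12:
            raise RangeError(
                f"interval [{lo}, {hi}] ms outside waveform span {waveform.span_ms}"
            )
        dt = waveform.dt_ms
        # snap to whole samples: floor for the start; ceil for the end,
        # excluded (half-open, like the sweep grid itself) so an interval
        # spanning whole cycles keeps the stimulus on an exact bin
        i0 = int(math.floor((lo - t[0]) / dt + 1e-12))
        i1 = min(int(math.ceil((hi - t[0]) / dt - 1e-12)), len(t))
        t = t[i0:i1]
        y = y[i0:i1]
    n = len(y)
    if n < 8:
        raise ParameterError(f"need at least 8 samples for a spectrum, got {n}")
    if zero_pad_factor < 1:
        raise ParameterError("zero_pad_factor must be >= 1")
    n_fft = n * int(zero_pad_factor)
    fs = waveform.sampling_rate_hz
    spec = np.fft.rfft(y, n=n_fft)
    amps = np.abs(spec) / n
    amps[1:] *= 2.0
    if n_fft % 2 == 0:
        amps[-1] /= 2.0  # Nyquist bin is not doubled
    freqs = np.fft.rfftfreq(n_fft, d=1.0 / fs)
    return Spectrum(
        frequencies_hz=freqs,
        amplitudes_uv=amps,
        resolution_hz=fs / n_fft,
        window_ms=(float(t[0]), float(t[-1])),
    )


def auto_mark_spectral_peaks(spectrum: Spectrum, n_peaks: int = 1) -> list[SpectralPeak]:
    """The ``n_peaks`` largest local maxima of the spectrum, DC excluded.

    Candidates are strict local maxima over the interior bins; the
    ``n_peaks`` with the largest amplitudes (ties to the lower frequency)
    are returned in ascending frequency order.
    """
    if n_peaks < 1:
        raise ParameterError("n_peaks must be >= 1")
    a = spectrum.amplitudes_uv
    interior = np.arange(1, len(a) - 1)
    is_max = (a[interior] > a[interior - 1]) & (a[interior] >= a[interior + 1])
    candidates = interior[is_max]
    candidates = candidates[candidates > 0]  # DC never a peak
    if len(candidates) < n_peaks:
        raise DetectionError(
            f"only {len(candidates)} spectral maxima found, {n_peaks} requested"
        )
    order = sorted(candidates.tolist(), key=lambda k: (-a[k], k))
    chosen = sorted(order[:n_peaks])
    return [
        SpectralPeak(
            frequency_hz=float(spectrum.frequencies_hz[k]),
            amplitude_uv=float(a[k]),
            bin_index=int(k),
            source="auto",
        )
        for k in chosen
    ]


def mark_spectral_peak(spectrum: Spectrum, frequency_hz: float) -> SpectralPeak:
    """Manual spectral mark: snap to the nearest bin and read its amplitude."""
    f = spectrum.frequencies_hz
    if frequency_hz < f[0] or frequency_hz > f[-1]:
        raise RangeError(
            f"frequency {frequency_hz} Hz outside spectrum range [{f[0]}, {f[-1]}] Hz"
        )
    k = int(np.argmin(np.abs(f - frequency_hz)))
    return SpectralPeak(
        frequency_hz=float(f[k]),
        amplitude_uv=float(spectrum.amplitudes_uv[k]),
        bin_index=k,
        source="manual",
    )
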