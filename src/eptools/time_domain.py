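"""Time-domain marking and morphological measures.

This module turns a sampled waveform into the measures an
evoked-potential reader cares about: marker placement (manual cursor or
automatic extremum detection), latency, amplitude, interpeak intervals,
the P1N1 area between a peak and its paired trough — by definite
integration of |y| and by the two-right-triangle approximation through the
zero-crossing — and the peak-to-trough slope.

Conventions
-----------
* Times are absolute milliseconds from sweep start; amplitudes are µV.
* Automatic markers always coincide with a sample point; manual markers
  may snap to the nearest sample or interpolate linearly.
* The zero baseline is 0 µV unless a ``baseline`` offset is given (real
  tracings sometimes ride on a DC offset).
* Areas are reported in µV·ms and are non-negative by construction.

Automatic extremum detection finds local maxima/minima by first-difference
sign change (a plateau is attributed to its first sample), ranks candidate
peak–trough pairs by prominence (vertical drop to the higher flanking
opposite extremum, computed per extremum), and breaks ties in favour of
earlier latency. This is deterministic and, on sampled sinusoids, lands on
the sample nearest the analytic extremum.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np


from .display import display_calculated, display_marked
from .errors import (
    DegenerateIntervalError,
    DetectionError,
    ParameterError,
    RangeError,
)
from .signals import Waveform

__all__ = [
    "MarkerKind",
    "Marker",
    "MarkedPair",
    "AreaResult",
    "MeasureSet",
    "auto_mark_extrema",
    "place_marker",
    "find_zero_cross",
    "absolute_area",
    "two_triangle_area",
    "slope",
    "interpeak_interval",
    "measure_pair",
    "pair_from_landmarks",
]


class MarkerKind(str, Enum):
    PEAK = "peak"
    TROUGH = "trough"
    ZERO_CROSS = "zero_cross"


@dataclass(frozen=True)
class Marker:
    """A labelled point on a waveform: kind, latency (ms), amplitude (µV)."""

    kind: MarkerKind
    time_ms: float
    amplitude_uv: float
    source: str = "auto"  # "auto" | "manual" | "analytic"
    label: str = ""

    @property
    def display_time(self) -> float:
        return display_marked(self.time_ms)

    @property
    def display_amplitude(self) -> float:
        return display_marked(self.amplitude_uv)


@dataclass(frozen=True)
class MarkedPair:
    """A peak and its paired trough, optionally with the zero-crossing."""

    peak: Marker
    trough: Marker
    zero: Marker | None = None

    def __post_init__(self) -> None:
        if not self.peak.time_ms < self.trough.time_ms:
            raise ParameterError("peak must precede trough")
        if self.zero is not None and not (
            self.peak.time_ms < self.zero.time_ms < self.trough.time_ms
        ):
            raise ParameterError("zero-cross must lie between peak and trough")

    def with_zero(self, zero: Marker) -> "MarkedPair":
        return MarkedPair(self.peak, self.trough, zero)


@dataclass(frozen=True)
class AreaResult:
    """An area measure (µV·ms) over an ordered interval (ms)."""

    method: str  # "integral" | "two_triangles"
    value_uv_ms: float
    interval_ms: tuple[float, float]

    def __post_init__(self) -> None:
        if self.value_uv_ms < 0:
            raise ParameterError("area must be non-negative")
        if not self.interval_ms[0] < self.interval_ms[1]:
            raise ParameterError("area interval must be ordered")

    @property
    def display_value(self) -> float:
        return display_calculated(self.value_uv_ms)


@dataclass
class MeasureSet:
    """All time-domain measures derived from one marked peak–trough pair."""

    latencies_ms: dict[str, float]
    amplitudes_uv: dict[str, float]
    peak_to_trough_amplitude_uv: float
    interpeak_intervals_ms: dict[str, float]
    slope_uv_per_ms: float
    areas: list[AreaResult] = field(default_factory=list)

    def area(self, method: str) -> AreaResult:
        for a in self.areas:
            if a.method == method:
                return a
        raise KeyError(method)


# ---------------------------------------------------------------------------
# marker placement and detection
# ---------------------------------------------------------------------------


def _window_slice(waveform: Waveform, window: tuple[float, float] | None) -> slice:
    if window is None:
        return slice(0, waveform.n_samples)
    lo, hi = window
    if not lo < hi:
        raise ParameterError("search window must be ordered")
    t = waveform.times
    i0 = int(np.searchsorted(t, lo, side="left"))
    i1 = int(np.searchsorted(t, hi, side="right"))
    if i1 - i0 < 3:
        raise DetectionError("search window holds fewer than 3 samples")
    return slice(i0, i1)


def _local_extrema(y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Indices of local maxima and minima by first-difference sign change.

    Zero differences (plateaus) inherit the sign of the next nonzero
    difference, so a plateau extremum is reported at its first sample.
    """
    d = np.sign(np.diff(y))
    nonzero = d != 0
    if not nonzero.all():
        # backward-fill zeros with the following nonzero sign (vectorized)
        nxt = np.where(nonzero, np.arange(d.size), d.size)
        nxt = np.minimum.accumulate(nxt[::-1])[::-1]
        filled = np.where(nxt < d.size, d[np.minimum(nxt, d.size - 1)], 0.0)
        d = filled
    interior = np.arange(1, len(y) - 1)
    rising_then_falling = (d[:-1] > 0) & (d[1:] < 0)
    falling_then_rising = (d[:-1] < 0) & (d[1:] > 0)
    return interior[rising_then_falling], interior[falling_then_rising]


def _flanking_prominence(
    y: np.ndarray, extrema: np.ndarray, opposite: np.ndarray, sign: int
) -> list[float]:
    """Prominence as the vertical drop to the higher (for peaks; lower for
    troughs) of the two flanking opposite-sign extrema.

    An extremum near the window edge may have only one flank; the existing
    flank is used alone, so the first cycle of a periodic wave is not
    penalized for abutting the sweep start.
    """
    proms: list[float] = []
    for e in extrema:
        left = opposite[opposite < e]
        right = opposite[opposite > e]
        flanks = []
        if len(left):
            flanks.append(y[left[-1]])
        if len(right):
            flanks.append(y[right[0]])
        if not flanks:
            proms.append(0.0)
        elif sign > 0:
            proms.append(float(y[e] - max(flanks)))
        else:
            proms.append(float(min(flanks) - y[e]))
    return proms


def auto_mark_extrema(
    waveform: Waveform,
    n_pairs: int = 1,
    search_window: tuple[float, float] | None = None,
) -> list[MarkedPair]:
    """Detect the ``n_pairs`` most prominent peak–trough pairs.

    Each peak is paired with the first trough that follows it; pairs are
    ranked by the smaller of the two prominences (ties broken by earlier
    peak latency) and returned in temporal order. Every marker lies on a
    sample point.
    """
    if n_pairs < 1:
        raise ParameterError("n_pairs must be >= 1")
    if waveform.n_samples < 3:
        raise ParameterError("waveform needs at least 3 samples")
    sl = _window_slice(waveform, search_window)
    t = waveform.times[sl]
    y = waveform.amplitudes[sl]

    peaks, troughs = _local_extrema(y)
    if len(peaks) == 0 or len(troughs) == 0:
        raise DetectionError("no peak/trough extrema found in the search window")

    peak_prom = _flanking_prominence(y, peaks, troughs, sign=+1)
    trough_prom = _flanking_prominence(y, troughs, peaks, sign=-1)
    trough_prom_at = dict(zip(troughs.tolist(), trough_prom))

    candidates = []  # (-min_prom, peak_time, peak_idx, trough_idx)
    for p, prom_p in zip(peaks, peak_prom):
        following = troughs[troughs > p]
        if len(following) == 0:
            continue
        q = int(following[0])
        rank = min(prom_p, trough_prom_at[q])
        candidates.append((-rank, float(t[p]), int(p), q))
    if len(candidates) < n_pairs:
        raise DetectionError(
            f"only {len(candidates)} peak–trough pairs available, "
            f"{n_pairs} requested"
        )
    candidates.sort()
    chosen = sorted(candidates[:n_pairs], key=lambda c: c[1])

    pairs = []
    for _, _, p, q in chosen:
        peak = Marker(MarkerKind.PEAK, float(t[p]), float(y[p]), source="auto")
        trough = Marker(MarkerKind.TROUGH, float(t[q]), float(y[q]), source="auto")
        pairs.append(MarkedPair(peak, trough))
    return pairs


def place_marker(
    waveform: Waveform,
    kind: MarkerKind | str,
    time_ms: float,
    snap: str = "nearest_sample",
) -> Marker:
    """Place a manual marker at ``time_ms``.

    ``snap="nearest_sample"`` adopts the nearest sample's (time, amplitude);
    ``snap="exact"`` keeps the requested time and interpolates the
    amplitude linearly.
    """
    kind = MarkerKind(kind)
    lo, hi = waveform.span_ms
    if not (lo <= time_ms <= hi):
        raise RangeError(f"time {time_ms} ms outside waveform span [{lo}, {hi}] ms")
    if snap == "nearest_sample":
        i = int(np.argmin(np.abs(waveform.times - time_ms)))
        return Marker(
            kind, float(waveform.times[i]), float(waveform.amplitudes[i]),
            source="manual",
        )
    if snap == "exact":
        amp = float(np.interp(time_ms, waveform.times, waveform.amplitudes))
        return Marker(kind, float(time_ms), amp, source="manual")
    raise ParameterError(f"unknown snap mode {snap!r}")


def find_zero_cross(
    waveform: Waveform, pair: MarkedPair, baseline: float = 0.0
) -> Marker:
    """Linearly interpolated baseline crossing between a pair's peak and trough.

    The first sign change of ``y - baseline`` in (peak, trough) is located
    and the crossing time interpolated between the bracketing samples; the
    returned marker has amplitude equal to the baseline.
    """
    t = waveform.times
    y = waveform.amplitudes - baseline
    i0 = int(np.searchsorted(t, pair.peak.time_ms, side="left"))
    i1 = int(np.searchsorted(t, pair.trough.time_ms, side="right"))
    seg_t = t[i0:i1]
    seg_y = y[i0:i1]
    if len(seg_t) < 2:
        raise DetectionError("peak–trough interval holds fewer than 2 samples")
    s = np.sign(seg_y)
    change = np.nonzero(s[:-1] * s[1:] < 0)[0]
    exact = np.nonzero(s == 0)[0]
    if len(exact) and (len(change) == 0 or exact[0] <= change[0]):
        tz = float(seg_t[exact[0]])
    elif len(change):
        j = int(change[0])
        tz = float(
            seg_t[j]
            - seg_y[j] * (seg_t[j + 1] - seg_t[j]) / (seg_y[j + 1] - seg_y[j])
        )
    else:
        raise DetectionError("no baseline crossing between peak and trough")
    return Marker(MarkerKind.ZERO_CROSS, tz, baseline, source=pair.peak.source)


# ---------------------------------------------------------------------------
# measures
# ---------------------------------------------------------------------------


def _interval_samples(
    waveform: Waveform, t0: float, t1: float, baseline: float
) -> tuple[np.ndarray, np.ndarray]:
    """Sample path from t0 to t1: exact endpoints (interpolated) plus all
    interior samples, with linearly interpolated baseline crossings inserted
    so the cusp of |y - baseline| lies on a node."""
    t = waveform.times
    y = waveform.amplitudes
    inner = (t > t0) & (t < t1)
    ts = np.concatenate(([t0], t[inner], [t1]))
    ys = np.interp(ts, t, y) - baseline
    s = np.sign(ys)
    cross = np.nonzero(s[:-1] * s[1:] < 0)[0]
    if len(cross):
        tz = ts[cross] - ys[cross] * (ts[cross + 1] - ts[cross]) / (
            ys[cross + 1] - ys[cross]
        )
        ts = np.insert(ts, cross + 1, tz)
        ys = np.insert(ys, cross + 1, 0.0)
    return ts, ys


def absolute_area(
    waveform: Waveform, pair: MarkedPair, baseline: float = 0.0
) -> AreaResult:
    """Integral of |y - baseline| from peak to trough (µV·ms).

    Composite trapezoid on the sampling grid, with the interval split at
    interpolated baseline crossings so the rectified cusp is honoured.
    """
    t0, t1 = pair.peak.time_ms, pair.trough.time_ms
    if t1 - t0 < waveform.dt_ms:
        raise DegenerateIntervalError(
            "peak–trough interval is shorter than one sample spacing"
        )
    ts, ys = _interval_samples(waveform, t0, t1, baseline)
    value = float(np.trapezoid(np.abs(ys), ts))
    return AreaResult("integral", value, (t0, t1))


def two_triangle_area(pair: MarkedPair) -> AreaResult:
    """Two-right-triangle approximation of the peak-to-trough area.

    (t_zero - t_peak)*|peak|/2 + (t_trough - t_zero)*|trough|/2, µV·ms.
    """
    if pair.zero is None:
        raise ParameterError("two_triangle_area needs a zero-cross marker")
    tp, tz, tt = pair.peak.time_ms, pair.zero.time_ms, pair.trough.time_ms
    value = (tz - tp) * abs(pair.peak.amplitude_uv) / 2.0 + (tt - tz) * abs(
        pair.trough.amplitude_uv
    ) / 2.0
    return AreaResult("two_triangles", value, (tp, tt))


def slope(pair: MarkedPair) -> float:
    """Peak-to-trough amplitude drop over the interval, µV/ms."""
    dt = pair.trough.time_ms - pair.peak.time_ms
    if dt <= 0:
        raise DegenerateIntervalError("slope needs a positive peak–trough interval")
    return (pair.peak.amplitude_uv - pair.trough.amplitude_uv) / dt


def interpeak_interval(a: Marker, b: Marker) -> float:
    """Signed latency difference b - a in ms."""
    return b.time_ms - a.time_ms


def pair_from_landmarks(landmarks) -> MarkedPair:
    """Build an analytic MarkedPair from a :class:`~eptools.signals.LandmarkSet`."""
    peak = Marker(
        MarkerKind.PEAK, landmarks.t_peak_ms, landmarks.peak_amplitude_uv,
        source="analytic",
    )
    trough = Marker(
        MarkerKind.TROUGH, landmarks.t_trough_ms, landmarks.trough_amplitude_uv,
        source="analytic",
    )
    zero = Marker(MarkerKind.ZERO_CROSS, landmarks.t_zero_ms, 0.0, source="analytic")
    return MarkedPair(peak, trough, zero)


def measure_pair(
    waveform: Waveform, pair: MarkedPair, baseline: float = 0.0
) -> MeasureSet:
    """All time-domain measures for one pair.

    Locates the zero-crossing if the pair lacks one, then computes
    latencies, amplitudes, the peak-to-trough amplitude and interval, the
    slope, and both area measures.
    """
    if pair.zero is None:
        pair = pair.with_zero(find_zero_cross(waveform, pair, baseline))
    return MeasureSet(
        latencies_ms={
            "peak": pair.peak.time_ms,
            "trough": pair.trough.time_ms,
            "zero_cross": pair.zero.time_ms,
        },
        amplitudes_uv={
            "peak": pair.peak.amplitude_uv,
            "trough": pair.trough.amplitude_uv,
        },
        peak_to_trough_amplitude_uv=pair.peak.amplitude_uv - pair.trough.amplitude_uv,
        interpeak_intervals_ms={
            "peak_trough": interpeak_interval(pair.peak, pair.trough)
        },
        slope_uv_per_ms=slope(pair),
        areas=[absolute_area(waveform, pair, baseline), two_triangle_area(pair)],
    )
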