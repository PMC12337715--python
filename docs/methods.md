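# Methods

## Scope and model

`eptools` analyses sampled evoked-potential sweeps — time series of
amplitude (µV) against time (ms) — and validates that analysis against
closed-form expectations on pure sinusoids. The package has no stochastic
component: every operation, from marking to reporting, is a deterministic
function of its inputs, and the end-to-end validation pipeline produces
byte-identical reports across runs.

The validation model is the zero-phase sinusoid `y(t) = A sin(2π f t)`.
Its first peak, zero-crossing and trough sit at `1/(4f)`, `1/(2f)` and
`3/(4f)`; the integral of `|y|` over the peak-to-trough half period is
`A/(πf)`; the two-triangle estimate through the zero-crossing is
`A/(4f) · 2`, i.e. exactly `π/4` of the integral; the slope is `4Af`.
These closed forms (`signals.analytic_landmarks`) are the oracle for every
downstream measure. A phase term is deliberately absent: the fixtures
are defined with zero phase, and the landmark algebra depends on it.

## Sampling grid

The standard fixture grid is 3072 samples spanning 10 ms with the
endpoint *excluded*: `t_k = k·10/3072` ms. This convention is a
deliberate choice among the two readings of "3072 points from 0 to
10 ms": it makes the sample spacing `10/3072` ms, puts an integer number
of cycles of 0.5/1/2 kHz in the window, and yields exact 100 Hz FFT bins,
so the stimulus frequencies land on bins 5/10/20 with zero leakage. An
endpoint-inclusive mode (`dt = 10/3071` ms) is provided as an option; it
destroys bin exactness and is not used by the fixtures.

## Marking

**Automatic extremum detection.** Local maxima/minima are found by
first-difference sign change; a plateau is attributed to its first
sample. Each peak is paired with the first trough after it. Pairs are
ranked by the smaller of the two prominences, where the prominence of an
extremum is the vertical distance to the higher (for peaks; lower for
troughs) of its two flanking opposite-sign extrema — with only the
existing flank used near the window edges, so the first cycle of a
periodic wave is not penalized for abutting the sweep start. Ties break
toward earlier latency, which selects the *first* peak–trough pair (the
clinically relevant P1N1) on any periodic waveform where all cycles are
equally prominent. The standard contour-based prominence (as in
`scipy.signal.peak_prominences`) was rejected for exactly this reason:
its left base for the first peak is the sweep edge, which halves that
peak's prominence and makes the detector skip to the second cycle.

**Manual placement** snaps to the nearest sample (adopting that sample's
time and amplitude) or, in `exact` mode, keeps the requested time and
interpolates the amplitude linearly.

**Zero-crossings** are located by linear interpolation between the two
samples bracketing the first sign change of `y − baseline` between a
pair's peak and trough. The baseline defaults to 0 µV; a configurable
offset accommodates real tracings riding on a DC shift.

## Measures and numerical choices

**Absolute area.** Composite trapezoid of `|y − baseline|` from the peak
marker to the trough marker: exact (interpolated) endpoint values, all
interior samples, and interpolated zero-crossings inserted as nodes so
the cusp of the rectified signal is honoured. The signed integral of a
sinusoid over that interval is ~0; the *absolute* integral is the
clinically meaningful quantity and the one the closed form `A/(πf)`
describes. Trapezoid error on these smooth fixtures is O(h²) (~5·10⁻⁵
µV·ms at 3072 samples); the dominant deviation from the closed form is
marker snapping to the grid, which is why the 500 Hz fixture reads
6.35–6.37 µV·ms depending on where the marks sit, against the analytic
6.366. An interval shorter than one sample spacing is rejected as
degenerate.

**Two-triangle area** is pure marker algebra and needs no grid. **Slope**
and **interpeak intervals** likewise. All derived measures are computed
from full-precision marker values, never from rounded displays.

**Display rounding.** Two conventions coexist in clinical reports and are
kept separate deliberately (`display.py`): marker readouts (latencies,
amplitudes, zero-crossings) display *rounded half-up* at 2 decimals,
while analytic expectations and calculated measures (areas, slopes)
display *truncated* at 2 decimals. This pairing is the unique one
consistent with the bundled validation tables (e.g. an auto-marked trough
at 0.748698 ms displaying 0.75, an analytic peak at 0.125 ms displaying
0.12, and a slope of 40.8163 displaying 40.81). Internal arithmetic is
always double precision; both the full value and the display value are
retained everywhere.

**Spectra.** Plain rectangular-window FFT, single-sided scaling
`2|Y_k|/N` (half at DC and, for even N, Nyquist); resolution `fs/N`.
Peak frequencies are reported as exact bin frequencies with no
interpolation. DC is excluded from peak search. Optional zero-padding
refines displayed bin spacing only; amplitudes keep the data-length
scaling. Time-interval selection snaps to whole samples, floor at the
start and ceiling at the end with the end excluded — half-open like the
sweep grid — so an interval spanning whole cycles keeps the stimulus on
an exact bin.

**Agreement metrics.** MAD and MAPE are elementwise means over aligned
label vectors; misaligned labels raise rather than reindex. MAPE is
stored as a dimensionless fraction and rendered with explicit
fraction/percent tags, because validation reports in this field often
print the fraction with a percent sign; propagating that ambiguity
silently would corrupt comparisons. The ICC is the two-way,
absolute-agreement, single-measure form ICC(A,1), computed from the
standard mean-squares decomposition; it is the conventional inter-rater
choice when systematic offsets between raters should count against
agreement. `pingouin`'s ICC serves as an independent cross-check in the
test suite, not as the implementation.

## File formats

Waveform tables are delimited text: first column time (ms), remaining
columns channels (µV), `#` comments skipped. The reader auto-detects
separator (comma, semicolon, tab), decimal mark (period, or comma as
common in Brazilian-locale exports) and header presence from the first
ten data lines; parsing is delegated to pandas, with ragged rows,
non-numeric cells and non-monotone time reported with 1-based line
numbers. The writer emits shortest round-trip decimals — deterministic,
byte-stable and lossless, which a fixed 6-significant-digit format is
not: truncating the time column would break the uniform-spacing invariant
(1e-9 relative) on a read-back. Markers persist in a sidecar table with
fixed columns (channel, kind, time, amplitude, source, label); the reader
does not judge marker validity against any waveform.

## Validation pipeline and what it shows

`validation.run_phase1_validation` regenerates the fixtures, recomputes
the automatic column with this implementation, and compares (a) the
recomputed values against analytic expectations and (b) the bundled
published rater columns (two human examiners and the original desktop
application's automatic marker) against the recorded expected column.
The published summary statistics — examiner calculation-row MAD 0.1111
and MAPE 0.0094, automatic calculation-row MAD 0.0100 and MAPE 0.0037,
examiner marking-row MAD 0.0009 — arise under the row-per-value
convention (11 marking rows, 9 calculation rows) and are reproduced
exactly at 4 decimals from path (b). Path (a) is gated by explicit
tolerances: marking rows must match displays exactly; areas within
0.04 µV·ms of the closed forms; slopes within 0.5%; spectral peaks on
exact bins within 1e-6 µV. The published examiner areas (6.33/3.05/1.56)
sit about one 10 µV-sample sliver (~0.033 µV·ms) below the analytic
values, a rounding artefact of the original integration rule that this
implementation does not replicate; the 0.04 µV·ms gate covers both.

The sinusoid fixtures exercise the full marking/measure/agreement chain
under ideal conditions: no noise, no baseline drift, no asymmetric
morphology. Passing them shows the arithmetic and conventions are
correct; it does not show robustness on real tracings, where detector
windowing, baseline offsets and rater variability dominate. The search
window and baseline parameters exist for that setting but are validated
here only structurally.

## Problem sizes

Tests and the acceptance script run at desk scale: 3072-sample sweeps for
all fixture work, a 10⁶-sample grid for the integration-convergence check
(closed form recovered within 1e-4 relative), 1500–2000-sample random
band-limited waveforms for detector-oracle equivalence, and ≤10-subject
rater matrices for ICC cross-checks. The whole suite completes in a few
seconds.

## Known limitations

* Phase-II style statistics on real clinical recordings (repeated-measures
  ANOVA, paired tests, effect sizes) are out of scope; the agreement
  harness is descriptive only.
* Difference-wave measures (MMN), binaural interaction, asymmetry
  indices, angles and area ratios are not implemented (no defining
  formulas in scope).
* The examiners' non-bin FFT frequency readings (502.07 Hz etc.) in the
  bundled tables come from a display/cursor mechanism that is not
  derivable from the data and is not reproduced; automatic spectral marks
  are exact bin frequencies.
* Tapered windows, PSD estimation and spectrograms are out of scope.
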