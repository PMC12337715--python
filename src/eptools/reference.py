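"""Published reference measurements for the sinusoid validation study.

The original desktop application this library re-implements was validated
against the 0.5/1/2 kHz, ±10 µV sinusoid fixtures: two trained human
examiners marked peaks and troughs on screen, the application's automatic
marker served as a third rater, and every derived measure was compared
with the analytic expectation. The printed result tables of that campaign
are bundled here as reference data — they are inputs to the agreement
harness (the human columns cannot be recomputed), and the expected column
doubles as a cross-check on this library's own analytic landmarks.

Two display conventions are baked into the printed values and are
preserved as-is: marked latencies/amplitudes are rounded half-up at 2
decimals, while analytic expectations and calculated measures (areas,
slopes) are truncated at 2 decimals (hence an expected 2 kHz peak latency
of 0.12 ms for the analytic 0.125, and a slope of 40.81 for 40.8163).

Label groups follow the harness convention of one comparison value per
printed row: 11 *marking* rows (latencies, one shared amplitude row per
polarity, zero-crossings) and 9 *calculation* rows (areas and slopes) in
the time domain; 12 rows in the frequency domain.
"""

from __future__ import annotations

from .agreement import MeasurementVector

__all__ = [
    "TIME_DOMAIN_ROWS",
    "FREQ_DOMAIN_ROWS",
    "MARKING_LABELS",
    "CALCULATION_LABELS",
    "FREQ_LABELS",
    "time_domain_expected",
    "time_domain_raters",
    "freq_domain_expected",
    "freq_domain_raters",
]

# label, expected, examiner 1, examiner 2, automatic (original application)
TIME_DOMAIN_ROWS: tuple[tuple[str, float, float, float, float], ...] = (
    ("500 Hz peak 1: latency (ms)",        0.5,   0.5,   0.5,   0.5),
    ("1000 Hz peak 1: latency (ms)",       0.25,  0.25,  0.25,  0.25),
    ("2000 Hz peak 1: latency (ms)",       0.12,  0.12,  0.12,  0.12),
    ("all freq peak 1: amplitude (µV)",    10.0,  10.0,  10.0,  10.0),
    ("500 Hz trough 1: latency (ms)",      1.5,   1.5,   1.5,   1.5),
    ("1000 Hz trough 1: latency (ms)",     0.75,  0.74,  0.74,  0.75),
    ("2000 Hz trough 1: latency (ms)",     0.37,  0.37,  0.37,  0.37),
    ("all freq trough 1: amplitude (µV)", -10.0, -10.0, -10.0, -10.0),
    ("500 Hz: zero-cross (ms)",            1.0,   1.0,   1.0,   1.0),
    ("1000 Hz: zero-cross (ms)",           0.5,   0.5,   0.5,   0.5),
    ("2000 Hz: zero-cross (ms)",           0.25,  0.25,  0.25,  0.25),
    ("500 Hz: area under curve (µV·ms)",   6.36,  6.33,  6.33,  6.33),
    ("1000 Hz: area under curve (µV·ms)",  3.18,  3.05,  3.05,  3.15),
    ("2000 Hz: area under curve (µV·ms)",  1.59,  1.56,  1.56,  1.56),
    ("500 Hz: area two triangles (µV·ms)", 5.0,   5.0,   5.0,   5.0),
    ("1000 Hz: area two triangles (µV·ms)", 2.5,  2.5,   2.5,   2.5),
    ("2000 Hz: area two triangles (µV·ms)", 1.25, 1.25,  1.25,  1.25),
    ("500 Hz: slope (µV/ms)",              20.0,  20.0,  20.0,  20.0),
    ("1000 Hz: slope (µV/ms)",             40.0,  40.81, 40.81, 40.0),
    ("2000 Hz: slope (µV/ms)",             80.0,  80.0,  80.0,  80.0),
)

FREQ_DOMAIN_ROWS: tuple[tuple[str, float, float, float, float], ...] = (
    ("500 Hz FFT: frequency (Hz)",      500.0,  502.07,  502.07,  500.0),
    ("500 Hz FFT: amplitude (µV)",       10.0,   10.0,    10.0,    10.0),
    ("1000 Hz FFT: frequency (Hz)",    1000.0,  998.96,  998.96, 1000.0),
    ("1000 Hz FFT: amplitude (µV)",      10.0,   10.0,    10.0,    10.0),
    ("2000 Hz FFT: frequency (Hz)",    2000.0, 1997.93, 1997.93, 2000.0),
    ("2000 Hz FFT: amplitude (µV)",      10.0,   10.0,    10.0,    10.0),
    ("sum FFT peak 1: frequency (Hz)",  500.0,  502.07,  502.07,  500.0),
    ("sum FFT peak 1: amplitude (µV)",   10.0,   10.0,    10.0,    10.0),
    ("sum FFT peak 2: frequency (Hz)", 1000.0,  998.96,  998.96, 1000.0),
    ("sum FFT peak 2: amplitude (µV)",   10.0,   10.0,    10.0,    10.0),
    ("sum FFT peak 3: frequency (Hz)", 2000.0, 1997.93, 1997.93, 2000.0),
    ("sum FFT peak 3: amplitude (µV)",   10.0,   10.0,    10.0,    10.0),
)

MARKING_LABELS: tuple[str, ...] = tuple(r[0] for r in TIME_DOMAIN_ROWS[:11])
CALCULATION_LABELS: tuple[str, ...] = tuple(r[0] for r in TIME_DOMAIN_ROWS[11:])
FREQ_LABELS: tuple[str, ...] = tuple(r[0] for r in FREQ_DOMAIN_ROWS)

RATER_NAMES = ("examiner 1", "examiner 2", "automatic")


def _vector(rows, column: int, name: str) -> MeasurementVector:
    return MeasurementVector(
        labels=tuple(r[0] for r in rows),
        values=tuple(float(r[column]) for r in rows),
        name=name,
    )


def time_domain_expected() -> MeasurementVector:
    return _vector(TIME_DOMAIN_ROWS, 1, "expected")


def time_domain_raters() -> dict[str, MeasurementVector]:
    return {
        name: _vector(TIME_DOMAIN_ROWS, 2 + i, name)
        for i, name in enumerate(RATER_NAMES)
    }


def freq_domain_expected() -> MeasurementVector:
    return _vector(FREQ_DOMAIN_ROWS, 1, "expected")


def freq_domain_raters() -> dict[str, MeasurementVector]:
    return {
        name: _vector(FREQ_DOMAIN_ROWS, 2 + i, name)
        for i, name in enumerate(RATER_NAMES)
    }
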