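"""Delimited-text I/O for waveform tables and marker sidecars.

Clinical evoked-potential systems export sweeps as plain text tables —
one time column (ms) followed by one amplitude column (µV) per channel.
Exports vary by locale: comma-separated with period decimals, or
semicolon/tab-separated with comma decimals (common in Brazilian
Portuguese locales). This module reads either, sniffing the dialect when
not told, and writes deterministic, bit-stable tables (6 significant
digits) so repeated runs are byte-identical.

Markers are persisted in a sidecar table with fixed columns
``channel, kind, time_ms, amplitude_uv, source, label``.

Lines starting with ``#`` are comments. Parsing itself is delegated to
pandas; this module adds dialect sniffing, validation (ragged rows,
non-numeric cells, non-increasing time) with line numbers, and the
domain containers.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import FormatError, ParameterError
from .signals import Waveform
from .time_domain import Marker, MarkerKind

__all__ = [
    "CsvDialect",
    "WaveformTable",
    "DEFAULT_DIALECT",
    "sniff_dialect",
    "read_waveform_table",
    "write_waveform_table",
    "read_markers",
    "write_markers",
]


@dataclass(frozen=True)
class CsvDialect:
    """Delimited-text dialect: separator, decimal mark, header, encoding."""

    separator: str = ","
    decimal: str = "."
    header: bool = True
    encoding: str = "utf-8"

    def __post_init__(self) -> None:
        if self.separator not in (",", ";", "\t"):
            raise ParameterError(f"unsupported separator {self.separator!r}")
        if self.decimal not in (".", ","):
            raise ParameterError(f"unsupported decimal mark {self.decimal!r}")
        if self.separator == self.decimal:
            raise ParameterError("field separator must differ from decimal mark")


DEFAULT_DIALECT = CsvDialect()


@dataclass
class WaveformTable:
    """One shared time axis (ms) and named amplitude channels (µV)."""

    times_ms: np.ndarray
    channels: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times_ms = np.asarray(self.times_ms, dtype=float)
        for name, values in self.channels.items():
            values = np.asarray(values, dtype=float)
            if len(values) != len(self.times_ms):
                raise ParameterError(
                    f"channel {name!r} length {len(values)} != time axis "
                    f"length {len(self.times_ms)}"
                )
            self.channels[name] = values

    @property
    def channel_names(self) -> list[str]:
        return list(self.channels)

    def waveform(self, name: str) -> Waveform:
        if name not in self.channels:
            raise KeyError(name)
        return Waveform(
            times=self.times_ms.copy(),
            amplitudes=self.channels[name].copy(),
            label=name,
            channel=name,
        )

    @classmethod
    def from_waveforms(cls, waveforms: list[Waveform]) -> "WaveformTable":
        if not waveforms:
            raise ParameterError("need at least one waveform")
        base = waveforms[0].times
        channels: dict[str, np.ndarray] = {}
        for i, w in enumerate(waveforms):
            if not np.array_equal(w.times, base):
                raise ParameterError("all waveforms must share one time axis")
            name = w.channel or w.label or f"ch{i + 1}"
            if name in channels:
                raise ParameterError(f"duplicate channel name {name!r}")
            channels[name] = w.amplitudes.copy()
        return cls(times_ms=base.copy(), channels=channels)


# ---------------------------------------------------------------------------
# dialect sniffing
# ---------------------------------------------------------------------------


def _data_lines(text: str) -> list[str]:
    return [ln for ln in text.splitlines() if ln.strip() and not ln.lstrip().startswith("#")]


def sniff_dialect(text: str, n_lines: int = 10) -> CsvDialect:
    """Infer separator and decimal mark from the first data lines.

    The separator is the candidate (tab, semicolon, comma) that splits
    every sampled line into the same number (>1) of fields; when comma
    ties with another candidate the non-comma one wins, since commas then
    are probably decimal marks. The decimal mark is a comma iff the
    separator is not a comma and commas appear inside fields.
    """
    lines = _data_lines(text)[:n_lines]
    if not lines:
        raise FormatError("empty input: no data lines to sniff")
    best = None
    for sep in ("\t", ";", ","):
        counts = {ln.count(sep) for ln in lines}
        if len(counts) == 1 and counts.pop() >= 1:
            best = sep
            break
    if best is None:
        raise FormatError("could not sniff a consistent field separator")
    decimal = "."
    if best != "," and any("," in f for ln in lines for f in ln.split(best)):
        decimal = ","
    first_fields = lines[0].split(best)

    def _numeric(tok: str) -> bool:
        tok = tok.strip().replace(decimal, ".") if decimal == "," else tok.strip()
        try:
            float(tok)
            return True
        except ValueError:
            return False

    header = not all(_numeric(f) for f in first_fields)
    return CsvDialect(separator=best, decimal=decimal, header=header)


# ---------------------------------------------------------------------------
# waveform tables
# ---------------------------------------------------------------------------


def _read_text(source) -> str:
    if hasattr(source, "read"):
        return source.read()
    path = os.fspath(source)
    with open(path, "r", encoding="utf-8") as fh:
        return fh.read()


def read_waveform_table(source, dialect: CsvDialect | None = None) -> WaveformTable:
    """Parse a delimited text table: first column time (ms), rest channels (µV).

    ``dialect=None`` sniffs separator, decimal mark and header presence.
    Raises :class:`FormatError` (naming the 1-based line) on ragged rows,
    non-numeric cells, or a non-increasing time column.
    """
    text = _read_text(source)
    if not _data_lines(text):
        raise FormatError("empty input: no data lines")
    if dialect is None:
        dialect = sniff_dialect(text)

    lines = text.splitlines()
    line_no = {}  # data-row index -> original 1-based line number
    row = 0
    header_seen = not dialect.header
    for i, ln in enumerate(lines, start=1):
        if not ln.strip() or ln.lstrip().startswith("#"):
            continue
        if not header_seen:
            header_seen = True
            continue
        line_no[row] = i
        row += 1

    try:
        frame = pd.read_csv(
            io.StringIO(text),
            sep=dialect.separator,
            decimal=dialect.decimal,
            header=0 if dialect.header else None,
            comment="#",
            skip_blank_lines=True,
            dtype=str,
        )
    except pd.errors.ParserError as exc:
        raise FormatError(f"malformed table: {exc}") from exc

    if frame.shape[1] < 2:
        raise FormatError("a waveform table needs a time column and >=1 channel")
    ragged = frame.isna().any(axis=1)
    if ragged.any():
        bad = int(np.nonzero(ragged.to_numpy())[0][0])
        raise FormatError(f"ragged row at line {line_no.get(bad, bad + 1)}")

    numeric = {}
    for col in frame.columns:
        cleaned = frame[col].str.strip()
        if dialect.decimal == ",":
            cleaned = cleaned.str.replace(",", ".", regex=False)
        values = pd.to_numeric(cleaned, errors="coerce")
        if values.isna().any():
            bad = int(np.nonzero(values.isna().to_numpy())[0][0])
            raise FormatError(
                f"non-numeric cell in column {col!r} at line {line_no.get(bad, bad + 1)}"
            )
        numeric[col] = values.to_numpy(dtype=float)

    cols = list(frame.columns)
    times = numeric[cols[0]]
    steps = np.diff(times)
    if np.any(steps <= 0):
        bad = int(np.nonzero(steps <= 0)[0][0]) + 1
        raise FormatError(
            f"time column not strictly increasing at line {line_no.get(bad, bad + 1)}"
        )
    names = (
        [str(c) for c in cols[1:]]
        if dialect.header
        else [f"ch{i}" for i in range(1, len(cols))]
    )
    channels = {name: numeric[col] for name, col in zip(names, cols[1:])}
    return WaveformTable(times_ms=times, channels=channels)


def _fmt(value: float, dialect: CsvDialect) -> str:
    # shortest round-trip decimal: deterministic, lossless, and keeps the
    # uniform-spacing invariant of the time axis through a file round trip
    s = repr(float(value))
    if dialect.decimal == ",":
        s = s.replace(".", ",")
    return s


def write_waveform_table(
    table: WaveformTable, dest, dialect: CsvDialect = DEFAULT_DIALECT
) -> None:
    """Write a table deterministically: shortest round-trip formatting,
    fixed column order (time first, channels in table order)."""
    if not table.channels or len(table.times_ms) == 0:
        raise FormatError("refusing to write an empty waveform table")
    sep = dialect.separator
    lines = []
    if dialect.header:
        lines.append(sep.join(["time_ms"] + table.channel_names))
    columns = [table.times_ms] + [table.channels[n] for n in table.channel_names]
    for row in zip(*columns):
        lines.append(sep.join(_fmt(v, dialect) for v in row))
    payload = "\n".join(lines) + "\n"
    if hasattr(dest, "write"):
        dest.write(payload)
    else:
        with open(os.fspath(dest), "w", encoding=dialect.encoding, newline="\n") as fh:
            fh.write(payload)


# ---------------------------------------------------------------------------
# marker sidecars
# ---------------------------------------------------------------------------

_MARKER_COLUMNS = ["channel", "kind", "time_ms", "amplitude_uv", "source", "label"]


def write_markers(
    markers: list[tuple[str, Marker]] | list[Marker],
    dest,
    dialect: CsvDialect = DEFAULT_DIALECT,
) -> None:
    """Persist markers, one per row. Accepts Markers or (channel, Marker) pairs."""
    sep = dialect.separator
    lines = [sep.join(_MARKER_COLUMNS)] if dialect.header else []
    for item in markers:
        channel, marker = item if isinstance(item, tuple) else ("", item)
        lines.append(
            sep.join(
                [
                    channel,
                    marker.kind.value,
                    _fmt(marker.time_ms, dialect),
                    _fmt(marker.amplitude_uv, dialect),
                    marker.source,
                    marker.label,
                ]
            )
        )
    payload = "\n".join(lines) + "\n" if lines else ""
    if hasattr(dest, "write"):
        dest.write(payload)
    else:
        with open(os.fspath(dest), "w", encoding=dialect.encoding, newline="\n") as fh:
            fh.write(payload)


def read_markers(
    source, dialect: CsvDialect | None = None
) -> list[tuple[str, Marker]]:
    """Read a marker sidecar; returns (channel, Marker) pairs in file order.

    The reader does not judge marker validity against any waveform — a
    marker outside a sweep's span is flagged downstream, not here. Unknown
    kind tokens are a :class:`FormatError`.
    """
    text = _read_text(source)
    lines = _data_lines(text)
    if not lines:
        return []
    if dialect is None:
        dialect = sniff_dialect(text)
    out: list[tuple[str, Marker]] = []
    start = 1 if dialect.header else 0
    for ln in lines[start:]:
        fields = ln.split(dialect.separator)
        if len(fields) < 5:
            raise FormatError(f"marker row has {len(fields)} fields, expected >=5")
        channel, kind_tok, time_tok, amp_tok, source_tok = (
            f.strip() for f in fields[:5]
        )
        label = fields[5].strip() if len(fields) > 5 else ""
        try:
            kind = MarkerKind(kind_tok)
        except ValueError as exc:
            raise FormatError(f"unknown marker kind {kind_tok!r}") from exc
        if dialect.decimal == ",":
            time_tok = time_tok.replace(",", ".")
            amp_tok = amp_tok.replace(",", ".")
        try:
            t = float(time_tok)
            a = float(amp_tok)
        except ValueError as exc:
            raise FormatError(f"non-numeric marker value in row {ln!r}") from exc
        out.append(
            (channel, Marker(kind=kind, time_ms=t, amplitude_uv=a,
                             source=source_tok, label=label))
        )
    return out
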