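"""Display-rounding conventions.

Clinical evoked-potential software reports two kinds of numbers and, in
practice, rounds them differently:

* **marked values** (latencies and amplitudes read off a cursor) are shown
  rounded half-up at 2 decimals — a cursor at 0.748698 ms reads "0.75";
* **calculated values** (areas, slopes, analytic expectations) are shown
  truncated at 2 decimals — a slope of 40.8163 µV/ms prints "40.81" and an
  analytic area of 6.36620 µV·ms prints "6.36".

Internal arithmetic always uses full double precision; these helpers only
format for reports. Both conventions round ties on the absolute value, so
-9.999972 displays as -10.00.
"""

from __future__ import annotations

from decimal import ROUND_DOWN, ROUND_HALF_UP, Decimal

__all__ = ["round_half_up", "truncate", "display_marked", "display_calculated"]


def round_half_up(value: float, decimals: int = 2) -> float:
    """Round to ``decimals`` places, ties away from zero (half-up on |x|)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def truncate(value: float, decimals: int = 2) -> float:
    """Drop digits beyond ``decimals`` places (toward zero)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_DOWN))


def display_marked(value: float, decimals: int = 2) -> float:
    """Display convention for marker readouts (latency/amplitude)."""
    return round_half_up(value, decimals)


def display_calculated(value: float, decimals: int = 2) -> float:
    """Display convention for derived measures (areas, slopes, expectations)."""
    return truncate(value, decimals)
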