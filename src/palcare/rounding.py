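"""Reporting-boundary rounding helpers.

All internal arithmetic in the pipeline keeps full float precision;
rounding happens exactly once, when a value is written to a report table.
Python's builtin ``round`` uses banker's rounding, which does not match the
half-up convention of published planning tables, so the helpers here go
through :mod:`decimal`.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def round_half_up(value: float, decimals: int = 0) -> float:
    """Round ``value`` to ``decimals`` places with ties rounding up.

    >>> round_half_up(2.5)
    3.0
    >>> round_half_up(1.845, 2)
    1.85
    """
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def fmt_half_up(value: float, decimals: int) -> str:
    """Format ``value`` rounded half-up with a fixed number of decimals."""
    q = Decimal(1).scaleb(-decimals)
    return str(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))
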