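"""Shared numeric helpers: half-up rounding and significant-figure formatting."""

from __future__ import annotations

import decimal


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with ties going away from zero, as in printed tables.

    Python's built-in ``round`` uses banker's rounding, which would turn
    9.375 into 9.38 rather than the conventional 9.4 at one decimal.
    """
    q = decimal.Decimal(1).scaleb(-ndigits)
    d = decimal.Decimal(repr(x)).quantize(q, rounding=decimal.ROUND_HALF_UP)
    return float(d)


def sigfig(x: float, n: int = 3) -> float:
    """Round ``x`` to ``n`` significant figures."""
    if x == 0:
        return 0.0
    d = decimal.Decimal(repr(x))
    shift = n - d.adjusted() - 1
    return float(round_half_up(x, shift))


def percent(numerator: int, denominator: int, ndigits: int = 1) -> float:
    """Percentage at printed precision (half-up)."""
    if denominator == 0:
        raise ZeroDivisionError("empty universe")
    return round_half_up(100.0 * numerator / denominator, ndigits)
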