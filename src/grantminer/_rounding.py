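"""Half-up rounding helpers.

All printed percentages in the pipeline use round-half-up (0.5 always
rounds away from zero), not banker's rounding, because that is the
convention that reproduces conventional hand-computed report tables.
Ratios of integers are rounded in exact decimal arithmetic so float
representation error can never flip a .5 boundary.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def round_half_up(value: float, decimals: int = 0) -> float:
    """Round ``value`` to ``decimals`` places, halves away from zero."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


def ratio_percent(count: int, denominator: int, decimals: int = 0) -> float:
    """``100 * count / denominator`` rounded half-up, in exact arithmetic."""
    if denominator == 0:
        raise ZeroDivisionError("denominator must be positive")
    q = Decimal(1).scaleb(-decimals)
    exact = (Decimal(count) * 100) / Decimal(denominator)
    return float(exact.quantize(q, rounding=ROUND_HALF_UP))
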