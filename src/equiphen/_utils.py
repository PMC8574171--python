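"""Small shared helpers."""

from __future__ import annotations

import decimal


def round_half_away(x: float, ndigits: int = 1) -> float:
    """Round with ties going away from zero, at ``ndigits`` decimals.

    Printed percentages in reports use this convention (53.763 -> 53.8),
    rather than Python's banker's rounding.
    """
    quantum = decimal.Decimal(1).scaleb(-ndigits)
    d = decimal.Decimal(repr(float(x))).quantize(
        quantum, rounding=decimal.ROUND_HALF_UP
    )
    return float(d)


def pct(numerator: float, denominator: float, ndigits: int = 1) -> float:
    """Percentage rounded half away from zero."""
    if denominator == 0:
        raise ZeroDivisionError("percentage with zero denominator")
    return round_half_away(100.0 * numerator / denominator, ndigits)
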