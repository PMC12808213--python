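"""Small shared reporting helpers (exact decimal percentages)."""

from __future__ import annotations

from decimal import Decimal, ROUND_HALF_EVEN

__all__ = ["percent"]


def percent(part: float, whole: float, ndigits: int = 2) -> float:
    """100 * part / whole, rounded half-even to ``ndigits`` decimals.

    Uses exact decimal arithmetic so printed-table proportions reproduce
    to the digit (e.g. 48/338 -> 14.20 at two decimals).
    """
    if whole == 0:
        raise ZeroDivisionError("percentage of an empty denominator")
    quantum = Decimal(1).scaleb(-ndigits)
    value = Decimal(100) * Decimal(str(part)) / Decimal(str(whole))
    return float(value.quantize(quantum, rounding=ROUND_HALF_EVEN))
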