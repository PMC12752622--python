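"""Small shared helpers."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round with ties away from zero, matching how clinical reports print
    percentages (Python's builtin ``round`` uses banker's rounding)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def percent(k: float, n: float, ndigits: int = 1) -> float:
    """``k/n`` expressed as a percentage rounded half-up to ``ndigits``."""
    if n == 0:
        raise ZeroDivisionError("percentage of an empty denominator")
    return round_half_up(100.0 * k / n, ndigits)
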