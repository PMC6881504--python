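"""Small shared numeric helpers."""

from __future__ import annotations

import decimal


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round with ties away from zero, the convention used for all reported
    percentages (Python's builtin ``round`` is banker's rounding)."""
    q = decimal.Decimal(10) ** -ndigits
    return float(decimal.Decimal(repr(x)).quantize(q, rounding=decimal.ROUND_HALF_UP))


def pct(numerator: float, denominator: float, ndigits: int = 2) -> float:
    """``100 * numerator / denominator`` rounded half-up to *ndigits*."""
    if denominator == 0:
        raise ZeroDivisionError("percentage with zero denominator")
    return round_half_up(100.0 * numerator / denominator, ndigits)
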