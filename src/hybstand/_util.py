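"""Small shared helpers."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def round_half_up(value: float, ndigits: int = 1) -> float:
    """Round with ties away from zero, the convention of printed field-survey rates.

    Python's built-in ``round`` is banker's rounding; reported percentages in
    this domain round 0.25 -> 0.3 at one decimal.
    """
    quantum = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(value))).quantize(quantum, rounding=ROUND_HALF_UP))
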