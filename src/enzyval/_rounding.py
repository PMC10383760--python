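"""Decimal rounding helpers.

Reported validation statistics are conventionally rounded half-away-from-zero
(3.776 -> 3.78, 4.224 -> 4.22), which differs from Python's built-in
round-half-even.  All user-facing rounding in this package goes through
:func:`round_half_away` so serialized reports match the convention used on
analytical certificates.  Statistics are always *computed* on unrounded
values; rounding happens only at presentation time.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def round_half_away(x: float, ndigits: int = 3) -> float:
    """Round ``x`` to ``ndigits`` decimals, ties going away from zero.

    Binary floats cannot represent decimal ties exactly: the mean of values
    entered with three decimals can come out as 1.65049999...96 where exact
    decimal arithmetic gives 1.6505.  Accumulated float error of that size is
    far below measurement resolution, so the value is first snapped to a
    guard precision (10 decimals past the target) before the half-away rule
    is applied, reproducing what decimal arithmetic on the entered values
    would give.
    """
    if x != x or x in (float("inf"), float("-inf")):  # NaN/inf pass through
        return x
    guard = Decimal(1).scaleb(-(ndigits + 10))
    q = Decimal(1).scaleb(-ndigits)
    snapped = Decimal(repr(x)).quantize(guard, rounding=ROUND_HALF_UP)
    return float(snapped.quantize(q, rounding=ROUND_HALF_UP))


def format_p_value(p: float, ndigits: int = 3) -> float:
    """Round a p-value for reporting; values below half an ulp render as 0.0."""
    return round_half_away(p, ndigits)
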