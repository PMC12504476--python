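"""Half-up decimal rounding, the convention that reproduces printed indices.

Python's built-in ``round`` is banker's rounding (2.675 -> 2.67); the printed
primary scores follow commercial half-up rounding (2/3 -> 0.67), so every
reported value in the package goes through :func:`round_half_up`.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal
from fractions import Fraction

__all__ = ["round_half_up", "to_decimal"]


def to_decimal(value: float | int | Fraction | Decimal) -> Decimal:
    """Exact Decimal view of *value* (Fractions divide at Decimal precision)."""
    if isinstance(value, Decimal):
        return value
    if isinstance(value, Fraction):
        return Decimal(value.numerator) / Decimal(value.denominator)
    if isinstance(value, int):
        return Decimal(value)
    return Decimal(repr(float(value)))


def round_half_up(value: float | int | Fraction | Decimal, ndigits: int = 2) -> float:
    """Round *value* to *ndigits* decimals, ties away from zero.

    >>> round_half_up(Fraction(2, 3))
    0.67
    >>> round_half_up(7.485)
    7.49
    """
    quantum = Decimal(1).scaleb(-ndigits)
    return float(to_decimal(value).quantize(quantum, rounding=ROUND_HALF_UP))
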