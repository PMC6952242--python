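"""Decimal-safe rounding to a display precision.

Clinical tools report distances quantized to a display precision (0.1 mm or
1 mm here).  Rounding is to the nearest multiple of the precision with ties
away from zero; going through `decimal` avoids binary-float artefacts such
as 3.45/0.1 evaluating just below 34.5.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

__all__ = ["round_to_multiple", "precision_decimals"]


def round_to_multiple(value: float, precision: float) -> float:
    """Nearest multiple of ``precision``, ties away from zero."""
    if precision <= 0:
        raise ValueError("precision must be positive")
    v = Decimal(repr(float(value)))
    p = Decimal(repr(float(precision)))
    n = (v / p).quantize(Decimal(1), rounding=ROUND_HALF_UP)
    return float(n * p)


def precision_decimals(precision: float) -> int:
    """Number of decimals needed to display multiples of ``precision``."""
    if precision <= 0:
        raise ValueError("precision must be positive")
    exponent = Decimal(repr(float(precision))).normalize().as_tuple().exponent
    return max(0, -int(exponent))
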