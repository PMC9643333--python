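"""Presentation rounding helpers.

Percentages are rounded to one decimal with half-up tie-breaking via exact
decimal arithmetic (float repr -> Decimal), so e.g. a column mean of 65.55
prints as 65.6 and 88.85 as 88.9.  Full precision is kept everywhere else.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable

__all__ = ["round1", "mean1"]


def round1(x: float) -> float:
    """Round to one decimal, ties away from zero, exactly in decimal."""
    return float(Decimal(repr(float(x))).quantize(Decimal("0.1"), ROUND_HALF_UP))


def mean1(values: Iterable[float]) -> float:
    """Exact-decimal arithmetic mean rounded to one decimal (half-up)."""
    decs = [Decimal(repr(float(v))) for v in values]
    if not decs:
        raise ValueError("mean of empty sequence")
    mean = sum(decs) / Decimal(len(decs))
    return float(mean.quantize(Decimal("0.1"), ROUND_HALF_UP))
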