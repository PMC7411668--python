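"""Shared helpers: rounding convention and logging setup."""

from __future__ import annotations

import logging
from decimal import ROUND_HALF_UP, Decimal

logger = logging.getLogger("weedpool")


def round_half_up(x: float, decimals: int = 0) -> float:
    """Round with ties away from zero at the given decimal place.

    Printed percentages and expected counts in this package use
    round-half-up (so 379.6 -> 380 and 39.75 -> 39.8), not banker's
    rounding, to match standard reporting practice in floristic tables.
    """
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def percent(count: float, total: float, decimals: int = 1) -> float:
    """Percentage of ``count`` over ``total``, rounded half-up."""
    if total <= 0:
        raise ValueError("percentage denominator must be positive")
    return round_half_up(100.0 * count / total, decimals)
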