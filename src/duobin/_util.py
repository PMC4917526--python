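"""Shared numeric helpers."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

import numpy as np


def round_half_up_ratio(numerator: int | float, denominator: int | float, decimals: int) -> float:
    """100 * numerator / denominator, rounded half-up to ``decimals`` places.

    Uses exact decimal arithmetic so printed-table values like 0.25 or 66.3
    reproduce regardless of binary float representation.
    """
    if denominator == 0:
        raise ZeroDivisionError("denominator must be positive")
    q = Decimal(100) * Decimal(str(numerator)) / Decimal(str(denominator))
    exp = Decimal(1).scaleb(-decimals)  # 10**-decimals
    return float(q.quantize(exp, rounding=ROUND_HALF_UP))


def round_half_up(value: float, decimals: int = 0) -> float:
    exp = Decimal(1).scaleb(-decimals)
    return float(Decimal(str(value)).quantize(exp, rounding=ROUND_HALF_UP))


def spawn_rngs(seed: int, n: int) -> list[np.random.Generator]:
    """Fan a global seed out into ``n`` independent, reproducible streams."""
    ss = np.random.SeedSequence(seed)
    return [np.random.Generator(np.random.PCG64(child)) for child in ss.spawn(n)]
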