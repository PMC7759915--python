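"""Reporting-precision helpers.

Report tables use half-up rounding to one decimal (the convention of the
source tables); internal computation always keeps full float precision.
"""

from __future__ import annotations

import math
from decimal import ROUND_HALF_UP, Decimal


def round_half_up(value: float, decimals: int = 1) -> float:
    """Round ``value`` half-up (away from zero at ties) to ``decimals`` places.

    Ties are decided on the shortest decimal representation of the float, so
    e.g. ``round_half_up(114.45, 1) == 114.5`` even though 114.45 has no exact
    binary representation.
    """
    if not math.isfinite(value):
        return float(value)
    quantum = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(value))).quantize(quantum, rounding=ROUND_HALF_UP))
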