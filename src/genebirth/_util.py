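"""Small shared numerics: rounding conventions used for printed figures."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def round_half_up(x: float, decimals: int = 2) -> float:
    """Round with ties away from zero (half-up), as in printed tables.

    Python's built-in ``round`` uses banker's rounding, which disagrees with
    figures quoted at fixed precision; all reported proportions and rates go
    through this helper instead.
    """
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))
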