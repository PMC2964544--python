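"""Small shared helpers: report rounding and p-value formatting."""

from __future__ import annotations

import math
from decimal import ROUND_HALF_UP, Decimal


def round_half_up(x: float, decimals: int = 1) -> float:
    """Round with ties going away from zero, as in printed clinical tables.

    Python/numpy default to banker's rounding, which turns 2.15 into 2.1;
    published score tables round it to 2.2. NaN passes through.
    """
    if x is None:
        return math.nan
    x = float(x)
    if math.isnan(x):
        return x
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def format_p(p: float, floor: float = 0.01, decimals: int = 3) -> str:
    """Render a p-value the way score-validation tables print it ("<0.01")."""
    if p is None or math.isnan(p):
        return "NA"
    if p < floor:
        return f"<{floor:g}"
    return f"{p:.{decimals}f}"
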