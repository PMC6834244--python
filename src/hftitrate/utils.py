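"""Small shared helpers."""
from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping


def percent(numerator: float, denominator: float, dp: int = 2) -> float:
    """Percentage with half-up rounding to ``dp`` decimals.

    Reports use half-up (commercial) rounding, not banker's rounding, so that
    e.g. 19.5 -> 20 at 0 dp. A zero denominator yields 0.0 rather than raising,
    which keeps empty reports well defined.
    """
    if denominator == 0:
        return 0.0
    q = Decimal(str(numerator)) * Decimal(100) / Decimal(str(denominator))
    exp = Decimal(1).scaleb(-dp)
    return float(q.quantize(exp, rounding=ROUND_HALF_UP))


def tabulate(counts: Mapping[str, int], denominator: int, dp: int = 0) -> dict[str, dict[str, float]]:
    """Turn category counts into ``{category: {count, percent}}`` on a fixed denominator.

    The denominator is passed explicitly because some summaries (e.g. nurse
    responses, where one reviewed proposal can carry several responses) use a
    denominator different from the sum of the counts.
    """
    return {
        k: {"count": int(c), "percent": percent(c, denominator, dp)}
        for k, c in counts.items()
    }
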