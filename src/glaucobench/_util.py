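"""Small numeric helpers used across modules."""

from __future__ import annotations

import math


def round_half_away(x: float) -> int:
    """Round to nearest integer, halves away from zero (0.5 -> 1, -0.5 -> -1)."""
    if x >= 0:
        return int(math.floor(x + 0.5))
    return int(math.ceil(x - 0.5))


def percent(count: float, total: float) -> int:
    """Integer percentage of ``count`` in ``total``, half-away-from-zero."""
    if total == 0:
        raise ZeroDivisionError("percentage with zero denominator")
    return round_half_away(100.0 * count / total)
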