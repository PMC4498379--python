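"""Integer percentage rules used throughout the reporting layer.

Two distinct rules are needed and must not be mixed:

* scalar percentages (a single numerator over a denominator, e.g. a host
  group's contribution) round half away from zero;
* percentage *rows* summarising a count vector are apportioned with the
  largest-remainder (Hamilton) method so the printed row sums to exactly
  100 — plain rounding of each cell can overshoot by one.
"""

from __future__ import annotations

import math
from collections.abc import Sequence


def round_half_away(x: float) -> int:
    """Round to the nearest integer, ties away from zero (2.5 -> 3, -2.5 -> -3)."""
    if x >= 0:
        return int(math.floor(x + 0.5))
    return -int(math.floor(-x + 0.5))


def pct(numerator: float, denominator: float) -> int:
    """Integer percentage of ``numerator / denominator``, half away from zero."""
    if denominator == 0:
        raise ZeroDivisionError("percentage denominator is zero")
    return round_half_away(100.0 * numerator / denominator)


def percentage_row(counts: Sequence[int], total: int | None = None) -> list[int]:
    """Integer percentage row over ``counts`` summing to exactly 100.

    Each cell is first rounded half away from zero. When the rounded row
    over- or undershoots 100, the difference is repaired on the rightmost
    cells whose rounding moved in the overshooting direction (an overshoot
    decrements rightmost rounded-up cells back to their floor, a deficit
    increments rightmost rounded-down cells to their ceiling). ``total``
    defaults to ``sum(counts)``.
    """
    if total is None:
        total = sum(counts)
    if total <= 0:
        raise ValueError("total must be positive")
    exact = [100.0 * c / total for c in counts]
    out = [round_half_away(e) for e in exact]
    excess = sum(out) - 100
    if excess > 0:
        rounded_up = [i for i, e in enumerate(exact) if out[i] > e]
        for i in reversed(rounded_up[-excess:] if excess <= len(rounded_up) else rounded_up):
            out[i] -= 1
            excess -= 1
        for i in reversed(range(len(out))):  # pathological leftovers
            if excess == 0:
                break
            if out[i] > 0:
                out[i] -= 1
                excess -= 1
    elif excess < 0:
        deficit = -excess
        rounded_down = [i for i, e in enumerate(exact) if out[i] < e]
        for i in reversed(rounded_down[-deficit:] if deficit <= len(rounded_down) else rounded_down):
            out[i] += 1
            deficit -= 1
        i = len(out) - 1
        while deficit > 0 and i >= 0:
            out[i] += 1
            deficit -= 1
            i -= 1
    return out
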