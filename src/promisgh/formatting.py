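"""Centralized rounding and rendering rules for reported numbers.

T-scores are reported to 1 decimal, thresholds as integers, percentages to
1 decimal — all rounded half-up (0.5 rounds away from zero toward the
larger value), matching how scoring manuals print conversion tables.
Internal computation is never rounded.
"""

from __future__ import annotations

import math
from typing import Iterable

import numpy as np


def round_half_up(x: float, decimals: int = 0) -> float:
    """Round with ties going up (2.5 -> 3), unlike banker's rounding."""
    if not math.isfinite(x):
        return x
    factor = 10.0**decimals
    return math.floor(x * factor + 0.5) / factor


def round_half_up_array(x: Iterable[float], decimals: int = 0) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    factor = 10.0**decimals
    return np.floor(arr * factor + 0.5) / factor


def fmt_tscore(t: float) -> str:
    return f"{round_half_up(t, 1):.1f}"


def fmt_percent(p: float) -> str:
    return f"{round_half_up(p, 1):.1f}"
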