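"""Anchor-based interpretability thresholds for T-scores.

The derivation uses a single general self-rated health item as anchor:

1. respondents are split into five groups by their anchor response
   (poor / fair / good / very good / excellent);
2. the mean subscale T-score of each group is computed;
3. each cut point is the midpoint of two adjacent group means, rounded
   half-up to an integer.

The four cut points ``t1 < t2 < t3 < t4`` tile the integer T axis into
five bands: poor (< t1), fair (t1 .. t2-1), good (t2 .. t3-1), very good
(t3 .. t4-1), excellent (>= t4).  Classification of a non-integer T-score
rounds it half-up to an integer first, since the bands are defined on
integers.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources
from typing import Sequence

import numpy as np

from promisgh.formatting import round_half_up

#: Anchor categories in increasing-health order (scored codes 1..5).
ANCHOR_LABELS = ("poor", "fair", "good", "very good", "excellent")


class ThresholdError(ValueError):
    pass


@dataclass(frozen=True)
class AnchorSummary:
    """Per-anchor-category n and mean T for one subscale.

    Categories are kept in fixed health order (poor -> excellent)
    regardless of how the means happen to be ordered in the sample; empty
    categories carry ``n = 0`` and a NaN mean and are listed in
    ``empty_categories``.
    """

    subscale_id: str
    n: tuple[int, ...]
    mean_t: tuple[float, ...]
    labels: tuple[str, ...] = ANCHOR_LABELS

    def __post_init__(self) -> None:
        if not (len(self.n) == len(self.mean_t) == len(self.labels) == 5):
            raise ThresholdError("anchor summary needs exactly 5 categories")

    @property
    def empty_categories(self) -> tuple[str, ...]:
        return tuple(l for l, n in zip(self.labels, self.n) if n == 0)


def anchor_group_means(
    tscores: Sequence[float], anchors: Sequence[int], subscale_id: str = ""
) -> AnchorSummary:
    """Mean T-score per anchor category (anchor codes 1..5, 5 = excellent)."""
    t = np.asarray(tscores, dtype=float)
    a = np.asarray(anchors)
    if t.shape != a.shape:
        raise ThresholdError(
            f"{t.size} T-scores but {a.size} anchor responses"
        )
    if not np.all(np.isin(a, range(1, 6))):
        bad = sorted(set(a[~np.isin(a, range(1, 6))].tolist()))
        raise ThresholdError(f"anchor values outside 1..5: {bad}")
    ns, means = [], []
    for code in range(1, 6):
        sel = t[a == code]
        ns.append(int(sel.size))
        means.append(float(sel.mean()) if sel.size else float("nan"))
    return AnchorSummary(subscale_id=subscale_id, n=tuple(ns), mean_t=tuple(means))


@dataclass(frozen=True)
class MidpointThresholds:
    """Four integer cut points plus the unrounded midpoints behind them."""

    thresholds: tuple[int, int, int, int]
    midpoints: tuple[float, float, float, float]
    warnings: tuple[str, ...] = ()


def midpoint_thresholds(summary: AnchorSummary) -> MidpointThresholds:
    """Cut points at midpoints of adjacent anchor-group means (half-up).

    All five category means must be defined.  Adjacent means that are not
    increasing with health produce a warning (no isotonic correction is
    applied) but still yield a value.
    """
    for label, n, m in zip(summary.labels, summary.n, summary.mean_t):
        if n == 0 or not np.isfinite(m):
            raise ThresholdError(
                f"anchor category {label!r} is empty; cannot take midpoints"
            )
    warnings = []
    midpoints, cuts = [], []
    for i in range(4):
        lo, hi = summary.mean_t[i], summary.mean_t[i + 1]
        if hi <= lo:
            warnings.append(
                f"anchor means not increasing between "
                f"{summary.labels[i]!r} ({lo:.2f}) and "
                f"{summary.labels[i + 1]!r} ({hi:.2f})"
            )
        mid = (lo + hi) / 2.0
        midpoints.append(mid)
        cuts.append(int(round_half_up(mid)))
    return MidpointThresholds(
        thresholds=tuple(cuts), midpoints=tuple(midpoints), warnings=tuple(warnings)
    )


@dataclass(frozen=True)
class ThresholdBands:
    """Five ordered health bands tiling the integer T axis."""

    thresholds: tuple[int, int, int, int]
    labels: tuple[str, ...] = ANCHOR_LABELS

    def __post_init__(self) -> None:
        t = self.thresholds
        if len(t) != 4 or any(x >= y for x, y in zip(t, t[1:])):
            raise ThresholdError(
                f"need four strictly increasing thresholds, got {t}"
            )

    def band_ranges(self) -> list[tuple[str, str]]:
        """Rendered (label, range) rows in poor -> excellent order."""
        t1, t2, t3, t4 = self.thresholds
        return [
            ("poor", f"< {t1}"),
            ("fair", f"{t1}-{t2 - 1}"),
            ("good", f"{t2}-{t3 - 1}"),
            ("very good", f"{t3}-{t4 - 1}"),
            ("excellent", f">= {t4}"),
        ]

    def classify(self, t: float) -> str:
        """Band label for a T-score (rounded half-up to an integer first)."""
        if not np.isfinite(t):
            raise ThresholdError("T-score must be finite")
        ti = int(round_half_up(t))
        t1, t2, t3, t4 = self.thresholds
        if ti < t1:
            return "poor"
        if ti < t2:
            return "fair"
        if ti < t3:
            return "good"
        if ti < t4:
            return "very good"
        return "excellent"


def format_bands(thresholds: Sequence[int]) -> ThresholdBands:
    """Validate four integer cut points and wrap them as labeled bands."""
    return ThresholdBands(thresholds=tuple(int(t) for t in thresholds))


def classify(t: float, bands: ThresholdBands) -> str:
    return bands.classify(t)


def derive_bands(
    tscores: Sequence[float], anchors: Sequence[int], subscale_id: str = ""
) -> tuple[ThresholdBands, MidpointThresholds, AnchorSummary]:
    """End-to-end: anchor grouping -> midpoints -> formatted bands."""
    summary = anchor_group_means(tscores, anchors, subscale_id=subscale_id)
    cuts = midpoint_thresholds(summary)
    return format_bands(cuts.thresholds), cuts, summary


def load_printed_thresholds() -> dict[tuple[str, str], ThresholdBands]:
    """Published cut points keyed by (population, subscale).

    Populations: ``NL`` (derived from the Dutch panel) and ``US`` (external
    comparison constants, stored verbatim).
    """
    text = (
        resources.files("promisgh.data").joinpath("thresholds_printed.csv").read_text()
    )
    out: dict[tuple[str, str], ThresholdBands] = {}
    rows = [
        r
        for r in csv.reader(text.splitlines())
        if r and not r[0].lstrip().startswith("#")
    ]
    for row in rows[1:]:
        pop, subscale, *cuts = [c.strip() for c in row]
        out[(pop, subscale)] = format_bands([int(c) for c in cuts])
    return out
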