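"""Cross-correlation lag analysis of edge and intensity time courses.

For two signals A and B sampled on the same uniform time grid, the CC
curve is the Pearson correlation of {A(t), B(t + tau)} over the overlap,
for every integer-frame lag tau within a bound.  A peak at positive lag
means A occurs earlier than B.  Per-cell peak lags are classified by sign,
and the population is summarized by the ratio of cells with positive lags
to cells with negative lags: a ratio above 1 means A leads B in the
majority of cells.  The analysis window follows the convention of taking
the time course from 5 min before to 30 min after stimulation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CCResult",
    "LagSummary",
    "cross_correlation",
    "find_peak",
    "lag_sign",
    "population_lag_ratio",
    "infer_event_order",
    "ANALYSIS_WINDOW_MIN",
]

ANALYSIS_WINDOW_MIN = (-5.0, 30.0)
DEFAULT_MAX_LAG_MIN = 15.0
MIN_OVERLAP = 8

#: event names for the canonical signal channels
EVENT_NAMES = {
    "Velocity": "extension initiation (velocity)",
    "Position": "stable extension (position)",
    "Intensity": "probe activation (intensity)",
}


@dataclass
class CCResult:
    """Lagged correlation curve between two time courses with its peak."""

    pair_label: str
    lags_min: np.ndarray
    cc: np.ndarray
    peak_lag_min: float
    peak_value: float
    cell_id: str = "cell"


@dataclass
class LagSummary:
    """Counts of cells with positive / negative / zero peak lags for a pair.

    ``ratio`` is n_positive / n_negative; when no cell has a negative lag
    the ratio is reported as ``inf`` (undefined-infinite marker) with the
    counts intact.
    """

    pair_label: str
    n_positive: int
    n_negative: int
    n_zero: int

    @property
    def ratio(self) -> float:
        if self.n_negative == 0:
            return math.inf if self.n_positive > 0 else math.nan
        return self.n_positive / self.n_negative


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return math.nan
    return float(((a - a.mean()) * (b - b.mean())).mean() / (sa * sb))


def cross_correlation(
    a: np.ndarray,
    b: np.ndarray,
    dt: float,
    max_lag_min: float = DEFAULT_MAX_LAG_MIN,
    pair_label: str = "A-B",
    cell_id: str = "cell",
    min_overlap: int = MIN_OVERLAP,
) -> CCResult:
    """CC curve of two signals on the same uniform time grid.

    For each integer-frame lag tau, cc(tau) is the Pearson correlation of
    {a(t), b(t + tau)} over the overlapping samples, with mean and SD
    computed on the overlap (a true correlation at every lag, unlike
    FFT-based estimators).  Positive peak lag means ``a`` precedes ``b``.
    Lags with fewer than ``min_overlap`` samples or zero variance are NaN
    and excluded from the peak search.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("a and b must be equal-length 1-D series")
    if dt <= 0:
        raise ValueError("dt must be positive")
    n = a.size
    m = int(math.floor(max_lag_min / dt))
    lags = np.arange(-m, m + 1)
    cc = np.full(lags.size, math.nan)
    for k, tau in enumerate(lags):
        if tau >= 0:
            aa, bb = a[: n - tau], b[tau:]
        else:
            aa, bb = a[-tau:], b[: n + tau]
        if aa.size < min_overlap:
            continue
        cc[k] = _pearson(aa, bb)
    lags_min = lags * dt
    peak_lag, peak_value = find_peak(lags_min, cc)
    return CCResult(
        pair_label=pair_label,
        lags_min=lags_min,
        cc=cc,
        peak_lag_min=peak_lag,
        peak_value=peak_value,
        cell_id=cell_id,
    )


def find_peak(
    lags_min: np.ndarray,
    cc: np.ndarray,
    lag_search_min: tuple[float, float] | None = None,
) -> tuple[float, float]:
    """Most positive correlation in the searched lag range and its lag.

    Ties are broken toward the lag of smallest absolute value (and toward
    the positive lag when magnitudes tie too).
    """
    lags_min = np.asarray(lags_min, dtype=float)
    cc = np.asarray(cc, dtype=float)
    sel = ~np.isnan(cc)
    if lag_search_min is not None:
        lo, hi = lag_search_min
        sel &= (lags_min >= lo) & (lags_min <= hi)
    if not sel.any():
        raise ValueError("no defined correlation values in the searched range")
    vmax = cc[sel].max()
    candidates = lags_min[sel & (cc == vmax)]
    order = np.lexsort((-candidates, np.abs(candidates)))
    return float(candidates[order[0]]), float(vmax)


def lag_sign(peak_lag_min: float, zero_tolerance_min: float = 0.0) -> str:
    """Classify a peak lag as 'positive', 'negative' or 'zero'."""
    if abs(peak_lag_min) <= zero_tolerance_min:
        return "zero"
    return "positive" if peak_lag_min > 0 else "negative"


def population_lag_ratio(signs: list[str], pair_label: str = "A-B") -> LagSummary:
    """Count per-cell lag signs and form the positive/negative ratio.

    Zero-lag cells are counted but excluded from both the numerator and the
    denominator of the ratio.
    """
    if not signs:
        raise ValueError("no cells")
    bad = set(signs) - {"positive", "negative", "zero"}
    if bad:
        raise ValueError(f"unknown lag signs: {bad}")
    return LagSummary(
        pair_label=pair_label,
        n_positive=signs.count("positive"),
        n_negative=signs.count("negative"),
        n_zero=signs.count("zero"),
    )


def infer_event_order(summaries: dict[str, LagSummary]) -> dict:
    """Order {velocity, position, probe intensity} events from lag ratios.

    Each pair summary "A-B" with ratio > 1 contributes the edge "A precedes
    B"; ratio < 1 the reverse; a ratio of exactly 1 or NaN omits the edge
    with a warning (an all-positive pair, ratio inf, counts as A-leads).
    Returns a dict with the precedence edges, a consistency flag, and —
    when the edges are acyclic — the event sequence by topological order.
    """
    edges: list[tuple[str, str]] = []
    nodes: set[str] = set()
    for label, s in summaries.items():
        first, second = (part.strip() for part in label.split("-", 1))
        nodes.update((first, second))
        r = s.ratio
        if math.isnan(r) or r == 1.0:
            warnings.warn(f"pair {label}: ratio undefined or tied; edge omitted")
            continue
        edges.append((first, second) if r > 1.0 else (second, first))
    # Kahn's algorithm on the tiny event graph
    remaining = {n: {a for a, b in edges if b == n} for n in nodes}
    order: list[str] = []
    while remaining:
        ready = sorted(n for n, preds in remaining.items() if not preds)
        if not ready:
            return {"consistent": False, "order": None, "edges": edges}
        n = ready[0]
        order.append(n)
        del remaining[n]
        for preds in remaining.values():
            preds.discard(n)
    named = [EVENT_NAMES.get(n, n) for n in order]
    return {"consistent": True, "order": named, "edges": edges}
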