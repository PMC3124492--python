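"""Spatiotemporal activity landscapes.

A landscape is the time x normalized-distance matrix of unit-sum intensity
profiles of one cell; landscapes of several cells can be interpolated to a
common time grid, averaged with the robust loess smoother into a population
surface, and divided by the pre-stimulation curve to remove time-constant
morphology and perinuclear bias (gauge invariance: multiplying the whole
landscape by any time-constant spatial function leaves the normalized
landscape unchanged).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocess import CellMask, FrameStack
from .profile import IntensityProfile, robust_loess

__all__ = [
    "Landscape",
    "PopulationSurface",
    "build_landscape",
    "resample_to_common_grid",
    "average_surface",
    "normalize_by_prestimulus",
    "ratio_frames",
]


@dataclass
class Landscape:
    """Time x normalized-distance matrix of profile values for one cell
    (or a population average)."""

    times_min: np.ndarray
    x_norm: np.ndarray
    values: np.ndarray
    cell_id: str = "cell"
    normalized: bool = False

    def __post_init__(self) -> None:
        self.times_min = np.asarray(self.times_min, dtype=float)
        self.x_norm = np.asarray(self.x_norm, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.times_min.size, self.x_norm.size):
            raise ValueError("values shape must be (n_times, n_x)")
        if np.any(np.diff(self.times_min) <= 0):
            raise ValueError("times must be strictly increasing")

    def to_frame(self) -> pd.DataFrame:
        """Long-format table (source, time_min, x_norm, value)."""
        t, x = np.meshgrid(self.times_min, self.x_norm, indexing="ij")
        return pd.DataFrame(
            {
                "source": self.cell_id,
                "time_min": t.ravel(),
                "x_norm": x.ravel(),
                "value": self.values.ravel(),
            }
        )


@dataclass
class PopulationSurface:
    """Average landscape plus the pooled contributing points kept for audit."""

    surface: Landscape
    points: pd.DataFrame


def build_landscape(profiles: list[IntensityProfile]) -> Landscape:
    """Stack one cell's profiles into a landscape, rows ordered by time."""
    if not profiles:
        raise ValueError("no profiles given")
    cell_ids = {p.cell_id for p in profiles}
    if len(cell_ids) != 1:
        raise ValueError("profiles from multiple cells")
    grid = profiles[0].x_norm
    for p in profiles[1:]:
        if p.x_norm.shape != grid.shape or not np.allclose(p.x_norm, grid):
            raise ValueError("profiles on different grids")
    times = np.array([p.time_min for p in profiles])
    if np.unique(times).size != times.size:
        raise ValueError("duplicate time stamps")
    order = np.argsort(times)
    values = np.stack([profiles[i].intensity for i in order])
    return Landscape(
        times_min=times[order],
        x_norm=grid.copy(),
        values=values,
        cell_id=profiles[0].cell_id,
    )


def resample_to_common_grid(
    landscapes: list[Landscape], times_out: np.ndarray
) -> pd.DataFrame:
    """Interpolate each cell's landscape in time onto a common time grid.

    Cells not covering a requested time are excluded at that time (no
    extrapolation).  Returns the pooled long-format point set
    (cell_id, time_min, x_norm, value).
    """
    times_out = np.asarray(times_out, dtype=float)
    rows = []
    for L in landscapes:
        t0, t1 = L.times_min[0], L.times_min[-1]
        for t in times_out:
            if t < t0 or t > t1:
                continue
            # linear interpolation between the bracketing rows
            interp = np.array(
                [np.interp(t, L.times_min, L.values[:, j]) for j in range(L.x_norm.size)]
            )
            rows.append(
                pd.DataFrame(
                    {
                        "cell_id": L.cell_id,
                        "time_min": t,
                        "x_norm": L.x_norm,
                        "value": interp,
                    }
                )
            )
    if not rows:
        raise ValueError("no cell covers any requested time")
    return pd.concat(rows, ignore_index=True)


def average_surface(
    points: pd.DataFrame,
    x_grid: np.ndarray | None = None,
    window: float = 0.10,
    min_points: int = 5,
) -> PopulationSurface:
    """Average curve per time point via robust degree-2 loess over all cells.

    At each time on the common grid a robust locally weighted quadratic
    regression is fitted through the pooled (x, value) points of every
    contributing cell and evaluated on ``x_grid``; fitted rows are clipped
    at zero and renormalized to unit sum so the average obeys the same
    contract as single-cell profiles.  Times with fewer than ``min_points``
    points are dropped with a warning.  Weighting is per point, so cells
    contributing more points weigh more.
    """
    if x_grid is None:
        x_grid = np.unique(points["x_norm"].to_numpy())
    x_grid = np.asarray(x_grid, dtype=float)
    times = np.unique(points["time_min"].to_numpy())
    kept_times, rows = [], []
    for t in times:
        sub = points[points["time_min"] == t]
        if len(sub) < min_points:
            warnings.warn(f"time {t} has fewer than {min_points} points; dropped")
            continue
        sub = sub.sort_values("x_norm")
        fitted = robust_loess(
            sub["x_norm"].to_numpy(),
            sub["value"].to_numpy(),
            window,
            degree=2,
            robust_iters=2,
            xout=x_grid,
        )
        fitted = np.clip(fitted, 0.0, None)
        total = fitted.sum()
        if total <= 0:
            warnings.warn(f"time {t}: fitted average is all zero; dropped")
            continue
        kept_times.append(t)
        rows.append(fitted / total)
    if not rows:
        raise ValueError("no time point had enough points to average")
    surface = Landscape(
        times_min=np.array(kept_times),
        x_norm=x_grid,
        values=np.stack(rows),
        cell_id="population",
    )
    return PopulationSurface(surface=surface, points=points)


def normalize_by_prestimulus(L: Landscape, eps: float = 0.01) -> Landscape:
    """Divide every row by the mean pre-stimulation curve.

    The reference is the mean of all rows with time < 0 (reducing to the
    single pre-stimulus row when only one exists).  Grid points where the
    reference falls below ``eps`` times its maximum are masked as NaN
    rather than amplified.
    """
    pre = L.times_min < 0
    if not pre.any():
        raise ValueError("no pre-stimulation rows to normalize against")
    reference = L.values[pre].mean(axis=0)
    guard = reference < eps * reference.max()
    ref = np.where(guard, np.nan, reference)
    values = L.values / ref
    return Landscape(
        times_min=L.times_min.copy(),
        x_norm=L.x_norm.copy(),
        values=values,
        cell_id=L.cell_id,
        normalized=True,
    )


def ratio_frames(
    numer: FrameStack, denom: FrameStack, masks: list[CellMask], eps_rel: float = 0.01
) -> np.ndarray:
    """Pixelwise two-channel ratio images inside the cell mask.

    Both stacks must be background-subtracted, aligned and on the same
    timebase.  Outside the mask, and wherever the denominator falls below
    ``eps_rel`` times its in-mask median, the ratio is NaN (undefined), not
    infinite.
    """
    if numer.frames.shape != denom.frames.shape:
        raise ValueError("channel stacks have different geometry")
    if (
        numer.frame_interval != denom.frame_interval
        or numer.stim_frame != denom.stim_frame
    ):
        raise ValueError("channel stacks have different timebases")
    if len(masks) != numer.n_frames:
        raise ValueError("need one mask per frame")
    out = np.full_like(numer.frames, np.nan)
    for f in range(numer.n_frames):
        m = masks[f].mask
        d = denom.frames[f]
        med = np.median(d[m]) if m.any() else 0.0
        valid = m & (d >= eps_rel * med) & (d > 0)
        out[f][valid] = numer.frames[f][valid] / d[valid]
    return out
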