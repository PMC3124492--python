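"""Free-end edge dynamics: position, velocity, and front intensity.

Because the cell is confined to a quasi-1-D strip, the free-end edge
position is simply the furthest mask pixel from the junction along x,
converted to micrometres.  Velocity is the central difference of position;
the maximal front intensity is the peak of the normalized profile within
the distal 10% of cell length.  All three time courses are smoothed with
the shared robust loess smoother (20-min window) before cross-correlation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocess import CellMask
from .profile import IntensityProfile, robust_loess

__all__ = [
    "EdgeSeries",
    "edge_position",
    "edge_velocity",
    "max_front_intensity",
    "smooth_timecourse",
    "qualifies_for_cc",
    "compute_edge_series",
]

FRONT_FRACTION = 0.10
TIME_SMOOTH_WINDOW_MIN = 20.0
MIN_EXTENSION_UM = 2.0


@dataclass
class EdgeSeries:
    """Per-cell time courses of edge position, velocity and front intensity."""

    times_min: np.ndarray
    position_um: np.ndarray
    velocity_um_per_min: np.ndarray
    front_intensity: np.ndarray
    cell_id: str = "cell"
    probe_label: str = "other"
    qualified: bool = True

    def __post_init__(self) -> None:
        self.times_min = np.asarray(self.times_min, dtype=float)
        self.position_um = np.asarray(self.position_um, dtype=float)
        self.velocity_um_per_min = np.asarray(self.velocity_um_per_min, dtype=float)
        self.front_intensity = np.asarray(self.front_intensity, dtype=float)
        n = self.times_min.size
        for arr in (self.position_um, self.velocity_um_per_min, self.front_intensity):
            if arr.size != n:
                raise ValueError("all channels must have equal length")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cell_id": self.cell_id,
                "time_min": self.times_min,
                "position_um": self.position_um,
                "velocity_um_min": self.velocity_um_per_min,
                "front_intensity": self.front_intensity,
                "qualified_flag": self.qualified,
            }
        )


def edge_position(mask: CellMask, junction_x: float, pixel_size: float) -> float:
    """Distance (um) from the junction to the furthest mask pixel along x."""
    cols = np.nonzero(mask.mask.any(axis=0))[0]
    if cols.size == 0:
        raise ValueError("empty mask")
    if junction_x > cols.min():
        raise ValueError("junction_x must not exceed the leftmost mask column")
    return float((cols.max() - junction_x) * pixel_size)


def edge_velocity(
    positions: np.ndarray, dt: float, scheme: str = "central"
) -> np.ndarray:
    """Edge velocity (um/min) by finite differences of the position series.

    ``central`` uses one-sided first-order differences at the two ends;
    ``forward``/``backward`` use the opposite one-sided difference at the
    series end where theirs is unavailable.
    """
    p = np.asarray(positions, dtype=float)
    if scheme == "central":
        if p.size < 3:
            raise ValueError("central difference needs at least 3 points")
        return np.gradient(p, dt)
    if scheme in ("forward", "backward"):
        if p.size < 2:
            raise ValueError("difference needs at least 2 points")
        d = np.diff(p) / dt
        if scheme == "forward":
            return np.concatenate([d, d[-1:]])
        return np.concatenate([d[:1], d])
    raise ValueError("scheme must be central, forward or backward")


def max_front_intensity(
    p: IntensityProfile, front_fraction: float = FRONT_FRACTION
) -> float:
    """Maximal profile intensity in the distal front region (default 10%
    of cell length at the free end)."""
    sel = p.x_norm >= 1.0 - front_fraction
    return float(p.intensity[sel].max())


def smooth_timecourse(
    times_min: np.ndarray,
    values: np.ndarray,
    window_min: float = TIME_SMOOTH_WINDOW_MIN,
    robust_iters: int = 2,
) -> np.ndarray:
    """Robust degree-2 loess over an absolute window on the time axis."""
    times_min = np.asarray(times_min, dtype=float)
    if times_min[-1] - times_min[0] < window_min:
        raise ValueError("time span shorter than the smoothing window")
    return robust_loess(
        times_min,
        values,
        window_min,
        degree=2,
        robust_iters=robust_iters,
        window_units="absolute",
    )


def qualifies_for_cc(
    positions: np.ndarray,
    stim_frame: int,
    min_extension_um: float = MIN_EXTENSION_UM,
) -> bool:
    """True iff the free end extends by more than ``min_extension_um``
    beyond its position at stimulation, at some post-stimulation frame."""
    p = np.asarray(positions, dtype=float)
    if not (0 <= stim_frame < p.size):
        raise ValueError("stim_frame outside the series")
    return bool((p[stim_frame:] - p[stim_frame]).max() > min_extension_um)


def compute_edge_series(
    masks: list[CellMask],
    profiles: list[IntensityProfile],
    junction_x: float,
    pixel_size: float,
    frame_interval: float,
    stim_frame: int,
    cell_id: str = "cell",
    probe_label: str = "other",
    front_fraction: float = FRONT_FRACTION,
    smooth: bool = True,
    velocity_scheme: str = "central",
) -> EdgeSeries:
    """Assemble the three smoothed time courses of one cell.

    Position is measured per frame, smoothed, differentiated with the
    chosen scheme, and the velocity smoothed again; front intensity comes
    from the per-frame normalized profiles and is smoothed likewise.  The
    qualification flag uses the raw (unsmoothed) position series.
    """
    if len(masks) != len(profiles):
        raise ValueError("need one profile per mask")
    n = len(masks)
    times = (np.arange(n) - stim_frame) * frame_interval
    pos_raw = np.array([edge_position(m, junction_x, pixel_size) for m in masks])
    fi_raw = np.array([max_front_intensity(p, front_fraction) for p in profiles])
    if smooth:
        pos = smooth_timecourse(times, pos_raw)
        vel = edge_velocity(pos, frame_interval, velocity_scheme)
        vel = smooth_timecourse(times, vel)
        fi = smooth_timecourse(times, fi_raw)
    else:
        pos = pos_raw
        vel = edge_velocity(pos, frame_interval, velocity_scheme)
        fi = fi_raw
    return EdgeSeries(
        times_min=times,
        position_um=pos,
        velocity_um_per_min=vel,
        front_intensity=fi,
        cell_id=cell_id,
        probe_label=probe_label,
        qualified=qualifies_for_cc(pos_raw, stim_frame),
    )
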