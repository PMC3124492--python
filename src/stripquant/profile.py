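"""Normalized 1-D intensity profiles and the shared robust loess smoother.

Each segmented frame of a strip-confined cell is collapsed to a 1-D curve of
mean fluorescence intensity versus normalized distance to the cell-cell
junction (0 = junction end, 1 = free end).  Cell length and total intensity
are both normalized to unity so that profiles from cells of different size,
expression level, or focus are directly comparable.

The module also hosts :func:`robust_loess`, the single locally weighted
regression smoother used throughout the pipeline: degree-1 with a 3-pixel
window for mask boundaries, robust degree-2 with a window of 10% of cell
length for spatial profiles, and robust degree-2 with a 20-min window for
time courses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "IntensityProfile",
    "y_average_profile",
    "normalize_profile",
    "robust_loess",
    "smooth_profile",
]

DEFAULT_GRID_SIZE = 101


@dataclass
class IntensityProfile:
    """Unit-sum intensity versus normalized distance-to-junction at one time.

    Attributes
    ----------
    x_norm : ndarray
        Uniform grid on [0, 1]; 0 is the junction end, 1 the free end.
    intensity : ndarray
        Nonnegative values on the grid, summing to 1.
    time_min : float
        Minutes relative to stimulation (negative = pre-stimulus).
    cell_id : str
    cell_length_um : float
        Physical junction-to-free-end length at this frame.
    """

    x_norm: np.ndarray
    intensity: np.ndarray
    time_min: float = 0.0
    cell_id: str = "cell"
    cell_length_um: float = float("nan")

    def __post_init__(self) -> None:
        self.x_norm = np.asarray(self.x_norm, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.x_norm.shape != self.intensity.shape:
            raise ValueError("x_norm and intensity must have the same length")
        if np.any(np.diff(self.x_norm) <= 0):
            raise ValueError("x_norm must be strictly increasing")
        if abs(self.x_norm[0]) > 1e-12 or abs(self.x_norm[-1] - 1.0) > 1e-12:
            raise ValueError("x_norm must span [0, 1]")
        if np.any(self.intensity < 0):
            raise ValueError("intensity must be nonnegative")
        total = self.intensity.sum()
        if not np.isclose(total, 1.0, atol=1e-9):
            raise ValueError(f"intensity must sum to 1 (got {total!r})")


def y_average_profile(
    frame: np.ndarray, mask: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Average intensity over the mask in the y-direction, column by column.

    Parameters
    ----------
    frame : 2-D array
        Background-subtracted intensity image.
    mask : 2-D bool array
        Cell mask of the same shape (a ``CellMask.mask`` is accepted too).

    Returns
    -------
    x_pixels, values
        The x-coordinates of columns intersecting the mask and, for each,
        the mean intensity over in-mask pixels of that column.
    """
    frame = np.asarray(frame, dtype=float)
    m = np.asarray(getattr(mask, "mask", mask)).astype(bool)
    if frame.shape != m.shape:
        raise ValueError("frame and mask shapes differ")
    counts = m.sum(axis=0)
    cols = np.nonzero(counts)[0]
    if cols.size == 0:
        raise ValueError("empty mask")
    sums = np.where(m, frame, 0.0).sum(axis=0)
    return cols.astype(float), sums[cols] / counts[cols]


def normalize_profile(
    x_pixels: np.ndarray,
    values: np.ndarray,
    junction_x: float,
    free_x: float,
    grid_size: int = DEFAULT_GRID_SIZE,
    *,
    pixel_size: float = 1.0,
    time_min: float = 0.0,
    cell_id: str = "cell",
) -> IntensityProfile:
    """Map a raw column profile onto the unit-length, unit-sum convention.

    x is mapped linearly so that ``junction_x`` lands at 0 and ``free_x`` at
    1, the values are resampled by linear interpolation onto a uniform
    ``grid_size``-point grid, and divided by their sum.
    """
    x_pixels = np.asarray(x_pixels, dtype=float)
    values = np.asarray(values, dtype=float)
    if free_x <= junction_x:
        raise ValueError("free_x must exceed junction_x")
    if np.any(values < 0):
        raise ValueError("values must be nonnegative")
    if not np.any(values > 0):
        raise ValueError("zero total intensity")
    u = (x_pixels - junction_x) / (free_x - junction_x)
    grid = np.linspace(0.0, 1.0, grid_size)
    resampled = np.interp(grid, u, values)
    total = resampled.sum()
    if total <= 0:
        raise ValueError("zero total intensity")
    return IntensityProfile(
        x_norm=grid,
        intensity=resampled / total,
        time_min=time_min,
        cell_id=cell_id,
        cell_length_um=(free_x - junction_x) * pixel_size,
    )


def _tricube(u: np.ndarray) -> np.ndarray:
    out = np.clip(1.0 - np.abs(u) ** 3, 0.0, None) ** 3
    return out


def _loess_pass(
    x: np.ndarray,
    y: np.ndarray,
    xout: np.ndarray,
    half_width: float,
    degree: int,
    robust_w: np.ndarray,
    min_pts: int,
) -> np.ndarray:
    n = x.size
    fitted = np.empty(xout.size)
    for k, x0 in enumerate(xout):
        d = np.abs(x - x0)
        idx = np.nonzero(d <= half_width)[0]
        if idx.size < min_pts:
            # series ends / sparse spots: fall back to the nearest min_pts
            idx = np.argpartition(d, min_pts - 1)[:min_pts]
        dd = d[idx]
        dmax = dd.max()
        w = _tricube(dd / dmax) if dmax > 0 else np.ones(idx.size)
        w = w * robust_w[idx]
        if np.count_nonzero(w) <= degree:
            w = w + 1e-8  # keep the local system solvable
        xc = x[idx] - x0
        design = np.vander(xc, degree + 1, increasing=True)
        sw = np.sqrt(w)
        coef, *_ = np.linalg.lstsq(design * sw[:, None], y[idx] * sw, rcond=None)
        fitted[k] = coef[0]
    return fitted


def robust_loess(
    x: np.ndarray,
    y: np.ndarray,
    window: float,
    degree: int = 2,
    robust_iters: int = 2,
    *,
    window_units: str = "fraction",
    xout: np.ndarray | None = None,
) -> np.ndarray:
    """Locally weighted polynomial regression with optional bisquare robustness.

    At every evaluation point a polynomial of the given degree is fitted by
    weighted least squares to the samples within the window, with tricube
    distance weights.  With ``robust_iters > 0`` the fit is iterated using
    bisquare robustness weights computed from the residuals (weight 0 beyond
    six times the median absolute residual), which suppresses gross outliers.

    Parameters
    ----------
    x, y : arrays
        Sample positions (sorted ascending) and values.
    window : float
        Window width, either as a fraction of the x-range
        (``window_units="fraction"``) or in the units of x
        (``window_units="absolute"``).
    degree : {1, 2}
        Local polynomial degree.
    robust_iters : int
        Number of bisquare reweighting iterations (0 = plain loess).
    xout : array, optional
        Positions at which to evaluate the fit; defaults to ``x``.

    Returns
    -------
    ndarray of fitted values at ``xout``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or x.shape != y.shape:
        raise ValueError("x and y must be equal-length 1-D arrays")
    if np.any(np.diff(x) < 0):
        raise ValueError("x must be sorted ascending")
    if window_units == "fraction":
        width = window * (x[-1] - x[0])
    elif window_units == "absolute":
        width = float(window)
    else:
        raise ValueError("window_units must be 'fraction' or 'absolute'")
    if width <= 0:
        raise ValueError("window must be positive")
    min_pts = degree + 2
    if x.size < min_pts:
        raise ValueError(f"need at least {min_pts} points for degree {degree}")
    half = width / 2.0
    # the window must hold a solvable fit somewhere in the interior
    counts = np.searchsorted(x, x + half, side="right") - np.searchsorted(
        x, x - half, side="left"
    )
    if counts.max() < min_pts:
        raise ValueError(
            f"window too small for degree-{degree} fit "
            f"(max {counts.max()} points per window, need {min_pts})"
        )
    robust_w = np.ones_like(y)
    fitted = _loess_pass(x, y, x, half, degree, robust_w, min_pts)
    for _ in range(robust_iters):
        resid = y - fitted
        # floor the bisquare scale at 1e-3 of the data range: residuals that
        # small are lack-of-fit, not outliers, and an unfloored scale makes
        # the reweighted fit unstable on (near-)noiseless data
        s = max(6.0 * np.median(np.abs(resid)), 1e-3 * np.ptp(y))
        if s <= 0:
            break
        u = np.clip(resid / s, -1.0, 1.0)
        robust_w = (1.0 - u**2) ** 2
        fitted = _loess_pass(x, y, x, half, degree, robust_w, min_pts)
    if xout is None:
        return fitted
    xout = np.asarray(xout, dtype=float)
    return _loess_pass(x, y, xout, half, degree, robust_w, min_pts)


def smooth_profile(
    p: IntensityProfile, window: float = 0.10, robust_iters: int = 2
) -> IntensityProfile:
    """Smooth a profile with robust degree-2 loess over 10% of cell length.

    Negative fitted values are clipped to zero and the result is
    renormalized to unit sum, preserving the profile contract.
    """
    fitted = robust_loess(
        p.x_norm, p.intensity, window, degree=2, robust_iters=robust_iters
    )
    fitted = np.clip(fitted, 0.0, None)
    total = fitted.sum()
    if total <= 0:
        raise ValueError("smoothing produced an all-zero profile")
    return IntensityProfile(
        x_norm=p.x_norm.copy(),
        intensity=fitted / total,
        time_min=p.time_min,
        cell_id=p.cell_id,
        cell_length_um=p.cell_length_um,
    )
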