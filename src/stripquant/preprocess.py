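"""Raw image stacks to aligned, background-subtracted, segmented cell masks.

The preprocessing chain mirrors standard single-cell fluorescence practice
for strip-confined cells: 3x3 median filtering, subtraction of a per-frame
background level measured in a fixed cell-free region, rotation so the strip
axis is horizontal with the free end pointing toward +x, Otsu thresholding
(one threshold per sequence, user-overridable), largest-component
segmentation with hole filling, and boundary extraction with a 3-pixel
lowess smoothing of the contour coordinates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from skimage import filters as _skfilters
from skimage import measure as _skmeasure

from .profile import robust_loess

__all__ = [
    "FrameStack",
    "BackgroundRegion",
    "CellMask",
    "Boundary",
    "estimate_background",
    "subtract_background",
    "median_filter_3x3",
    "rotate_align",
    "otsu_threshold",
    "segment",
    "extract_boundary",
]


@dataclass
class FrameStack:
    """Calibrated time-lapse intensity frames.

    ``frames`` has shape (T, H, W); ``pixel_size`` is um/pixel,
    ``frame_interval`` min/frame, and ``stim_frame`` the index of the first
    post-stimulation frame (so frame f is at (f - stim_frame) *
    frame_interval minutes relative to stimulation).
    """

    frames: np.ndarray
    pixel_size: float
    frame_interval: float
    stim_frame: int
    channel_label: str = ""

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (T, H, W) array")
        if self.pixel_size <= 0 or self.frame_interval <= 0:
            raise ValueError("pixel_size and frame_interval must be positive")
        if not (0 <= self.stim_frame < self.n_frames):
            raise ValueError("stim_frame out of range")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    def times_min(self) -> np.ndarray:
        """Frame times in minutes relative to stimulation."""
        return (np.arange(self.n_frames) - self.stim_frame) * self.frame_interval


@dataclass
class BackgroundRegion:
    """A fixed cell-free region used for the whole sequence.

    Stored as a boolean mask over the frame geometry; one outline serves
    every frame so background-subtracted images need not be stored.
    """

    mask: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask).astype(bool)
        if self.mask.ndim != 2:
            raise ValueError("background region mask must be 2-D")
        if not self.mask.any():
            raise ValueError("empty background region")

    @classmethod
    def from_rectangle(
        cls, shape: tuple[int, int], x0: int, y0: int, x1: int, y1: int
    ) -> "BackgroundRegion":
        """Rectangle with inclusive corners (x0, y0)-(x1, y1)."""
        h, w = shape
        if not (0 <= x0 <= x1 < w and 0 <= y0 <= y1 < h):
            raise ValueError("background rectangle outside frame bounds")
        m = np.zeros(shape, dtype=bool)
        m[y0 : y1 + 1, x0 : x1 + 1] = True
        return cls(m)


@dataclass
class CellMask:
    """Per-frame binary segmentation with the threshold that produced it."""

    mask: np.ndarray
    threshold: float
    frame_index: int = 0

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask).astype(bool)


@dataclass
class Boundary:
    """Ordered closed contour of a cell mask, coordinates in pixels (x, y)."""

    points: np.ndarray
    smoothing_window_px: int = 3

    def area(self) -> float:
        """Enclosed area by the shoelace formula."""
        x = self.points[:, 0]
        y = self.points[:, 1]
        return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def estimate_background(
    stack: FrameStack, region: BackgroundRegion
) -> np.ndarray:
    """Mean intensity over the background region, one value per frame."""
    if region.mask.shape != stack.shape:
        raise ValueError("background region outside frame bounds")
    flat = stack.frames[:, region.mask]
    return flat.mean(axis=1)


def subtract_background(stack: FrameStack, levels: np.ndarray) -> FrameStack:
    """Subtract per-frame scalar backgrounds, clipping negatives to zero."""
    levels = np.asarray(levels, dtype=float)
    if levels.shape != (stack.n_frames,):
        raise ValueError("levels length must equal frame count")
    frames = np.clip(stack.frames - levels[:, None, None], 0.0, None)
    return replace(stack, frames=frames)


def median_filter_3x3(frame: np.ndarray) -> np.ndarray:
    """3x3 median filter with edge replication at the borders."""
    frame = np.asarray(frame, dtype=float)
    if frame.ndim != 2 or min(frame.shape) < 3:
        raise ValueError("frame must be at least 3x3")
    return ndimage.median_filter(frame, size=3, mode="nearest")


def rotate_align(
    stack: FrameStack, angle_deg: float, junction_side: str = "left"
) -> FrameStack:
    """Rotate so the strip axis is horizontal, free end toward +x.

    ``angle_deg`` is the counterclockwise rotation applied to each frame
    (chosen per cell so the strip lands on the x-axis); when the junction is
    on the right the rotated frames are mirrored horizontally so the free
    end always points to +x.  Bilinear interpolation; the canvas grows to
    hold the rotated image.
    """
    if not np.isfinite(angle_deg):
        raise ValueError("rotation angle must be finite")
    if junction_side not in ("left", "right"):
        raise ValueError("junction_side must be 'left' or 'right'")
    if angle_deg % 360.0 == 0.0:
        frames = stack.frames.copy()
    else:
        frames = np.stack(
            [
                ndimage.rotate(
                    f, angle_deg, reshape=True, order=1, mode="constant", cval=0.0
                )
                for f in stack.frames
            ]
        )
        frames = np.clip(frames, 0.0, None)
    if junction_side == "right":
        frames = frames[:, :, ::-1].copy()
    return replace(stack, frames=frames)


def otsu_threshold(frame: np.ndarray) -> float:
    """Otsu's threshold on a 256-bin histogram over the observed range.

    Returns the threshold maximizing the between-class variance; pixels at
    or above it are foreground under :func:`segment`.
    """
    frame = np.asarray(frame, dtype=float)
    if frame.min() == frame.max():
        raise ValueError("degenerate histogram: frame is constant")
    return float(_skfilters.threshold_otsu(frame, nbins=256))


def segment(
    frame: np.ndarray, threshold: float, frame_index: int = 0
) -> CellMask:
    """Binarize at the threshold, keep the largest 4-connected component,
    and fill fully enclosed holes."""
    frame = np.asarray(frame, dtype=float)
    fg = frame >= threshold
    if not fg.any():
        raise ValueError("no cell found")
    labels = _skmeasure.label(fg, connectivity=1)
    sizes = np.bincount(labels.ravel())
    sizes[0] = 0
    mask = labels == sizes.argmax()
    mask = ndimage.binary_fill_holes(mask)
    return CellMask(mask=mask, threshold=float(threshold), frame_index=frame_index)


def extract_boundary(mask: CellMask, smoothing_window_px: int = 3) -> Boundary:
    """Ordered closed contour of the mask, coordinates lowess-smoothed.

    Each coordinate channel of the sub-pixel contour is smoothed with a
    degree-1 locally weighted fit over a ``smoothing_window_px`` window
    (periodic: the contour is padded circularly before smoothing).
    """
    m = mask.mask
    h, w = m.shape
    if m[0].any() and m[-1].any() and m[:, 0].any() and m[:, -1].any():
        warnings.warn("mask touches all four image borders (possible crop error)")
    # zero-pad so masks touching the image border still yield a closed contour
    padded = np.pad(m.astype(float), 1)
    contours = _skmeasure.find_contours(padded, 0.5)
    if not contours:
        raise ValueError("no boundary found for mask")
    contour = max(contours, key=len) - 1.0  # (row, col) vertices, closed
    if np.allclose(contour[0], contour[-1]):
        contour = contour[:-1]
    xy = contour[:, ::-1]  # -> (x, y)
    n = len(xy)
    if n < 8:
        return Boundary(points=xy, smoothing_window_px=smoothing_window_px)
    pad = max(smoothing_window_px, 3)
    t = np.arange(-pad, n + pad, dtype=float)
    smoothed = np.empty_like(xy)
    for c in range(2):
        vals = np.concatenate([xy[-pad:, c], xy[:, c], xy[:pad, c]])
        fit = robust_loess(
            t,
            vals,
            float(smoothing_window_px),
            degree=1,
            robust_iters=0,
            window_units="absolute",
        )
        smoothed[:, c] = fit[pad : pad + n]
    return Boundary(points=smoothed, smoothing_window_px=smoothing_window_px)
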