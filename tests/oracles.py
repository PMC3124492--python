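"""Independent brute-force oracles used to pin operation semantics."""

import numpy as np


def otsu_exhaustive(frame: np.ndarray, nbins: int = 256) -> float:
    """Exhaustive search of the between-class-variance maximizer.

    Enumerates every histogram split point, computing class weights and
    means directly from the histogram, and returns the bin center of the
    best lower class — independent of any library Otsu implementation.
    """
    frame = np.asarray(frame, dtype=float)
    counts, edges = np.histogram(frame.ravel(), bins=nbins)
    centers = (edges[:-1] + edges[1:]) / 2.0
    best_var, best_thresh = -1.0, centers[0]
    total = counts.sum()
    for k in range(nbins - 1):
        w0 = counts[: k + 1].sum()
        w1 = total - w0
        if w0 == 0 or w1 == 0:
            continue
        mu0 = (counts[: k + 1] * centers[: k + 1]).sum() / w0
        mu1 = (counts[k + 1 :] * centers[k + 1 :]).sum() / w1
        var = w0 * w1 * (mu0 - mu1) ** 2
        if var > best_var:
            best_var, best_thresh = var, centers[k]
    return float(best_thresh)


def otsu_variance_curve(frame: np.ndarray, nbins: int = 256):
    """Between-class variance at every candidate split, computed directly."""
    frame = np.asarray(frame, dtype=float)
    counts, edges = np.histogram(frame.ravel(), bins=nbins)
    centers = (edges[:-1] + edges[1:]) / 2.0
    total = counts.sum()
    var = np.full(nbins - 1, -np.inf)
    for k in range(nbins - 1):
        w0 = counts[: k + 1].sum()
        w1 = total - w0
        if w0 == 0 or w1 == 0:
            continue
        mu0 = (counts[: k + 1] * centers[: k + 1]).sum() / w0
        mu1 = (counts[k + 1 :] * centers[k + 1 :]).sum() / w1
        var[k] = w0 * w1 * (mu0 - mu1) ** 2
    return centers, var


def median3x3_exhaustive(frame: np.ndarray) -> np.ndarray:
    """Per-pixel 3x3 neighborhood median with edge replication."""
    padded = np.pad(np.asarray(frame, dtype=float), 1, mode="edge")
    out = np.empty_like(np.asarray(frame, dtype=float))
    h, w = out.shape
    for i in range(h):
        for j in range(w):
            out[i, j] = np.median(padded[i : i + 3, j : j + 3])
    return out
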