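"""End-to-end orchestration: stacks -> masks -> profiles -> landscapes ->
edge series -> cross-correlation summaries.

`quantify_stack` runs the per-cell chain in memory; `correlate_cohort`
turns a cohort's edge series into CC curves, peak lags and lag-count
ratios; `run_pipeline` drives a whole cohort from a YAML config with
per-cell fault isolation and writes the CSV/JSON/PNG outputs plus a run
manifest that echoes every effective parameter.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import __version__
from .correlation import (
    ANALYSIS_WINDOW_MIN,
    DEFAULT_MAX_LAG_MIN,
    CCResult,
    LagSummary,
    cross_correlation,
    infer_event_order,
    lag_sign,
    population_lag_ratio,
)
from .edge import EdgeSeries, compute_edge_series
from .landscape import (
    Landscape,
    PopulationSurface,
    average_surface,
    build_landscape,
    normalize_by_prestimulus,
    resample_to_common_grid,
)
from .preprocess import (
    BackgroundRegion,
    CellMask,
    FrameStack,
    estimate_background,
    extract_boundary,
    median_filter_3x3,
    otsu_threshold,
    rotate_align,
    segment,
    subtract_background,
)
from .profile import (
    DEFAULT_GRID_SIZE,
    IntensityProfile,
    normalize_profile,
    smooth_profile,
    y_average_profile,
)

logger = logging.getLogger("stripquant")

CANONICAL_PAIRS = ("Velocity-Intensity", "Position-Intensity", "Position-Velocity")


@dataclass
class CellResult:
    """Everything the per-cell chain produces for one movie."""

    cell_id: str
    masks: list[CellMask]
    profiles: list[IntensityProfile]
    landscape: Landscape
    edge: EdgeSeries
    threshold: float
    junction_x: float


def quantify_stack(
    stack: FrameStack,
    cell_id: str = "cell",
    *,
    background_region: BackgroundRegion | None = None,
    rotation_deg: float = 0.0,
    junction_side: str = "left",
    threshold_override: float | None = None,
    junction_x: float | None = None,
    grid_size: int = DEFAULT_GRID_SIZE,
    front_fraction: float = 0.10,
    probe_label: str = "other",
    apply_median_filter: bool = True,
    smooth_timecourses: bool = True,
) -> CellResult:
    """Run preprocessing, profiling and edge extraction on one stack.

    One threshold serves the whole sequence: the user override when given,
    otherwise Otsu on the first pre-stimulation frame.  The junction
    column defaults to the leftmost mask column of that reference frame.
    """
    if apply_median_filter:
        frames = np.stack([median_filter_3x3(f) for f in stack.frames])
        stack = FrameStack(
            frames,
            stack.pixel_size,
            stack.frame_interval,
            stack.stim_frame,
            stack.channel_label,
        )
    if background_region is not None:
        levels = estimate_background(stack, background_region)
        stack = subtract_background(stack, levels)
    stack = rotate_align(stack, rotation_deg, junction_side)

    ref_frame = stack.frames[0]
    threshold = (
        float(threshold_override)
        if threshold_override is not None
        else otsu_threshold(ref_frame)
    )
    masks = [segment(stack.frames[f], threshold, f) for f in range(stack.n_frames)]
    if junction_x is None:
        # the junction end is stationary: take the leftmost mask column
        # over the whole sequence so it bounds every frame
        junction_x = float(
            min(np.nonzero(m.mask.any(axis=0))[0].min() for m in masks)
        )

    times = stack.times_min()
    profiles = []
    for f, mask in enumerate(masks):
        cols, vals = y_average_profile(stack.frames[f], mask)
        free_x = cols.max()
        p = normalize_profile(
            cols,
            vals,
            junction_x,
            free_x,
            grid_size,
            pixel_size=stack.pixel_size,
            time_min=times[f],
            cell_id=cell_id,
        )
        profiles.append(smooth_profile(p))
    L = build_landscape(profiles)
    edge = compute_edge_series(
        masks,
        profiles,
        junction_x,
        stack.pixel_size,
        stack.frame_interval,
        stack.stim_frame,
        cell_id=cell_id,
        probe_label=probe_label,
        front_fraction=front_fraction,
        smooth=smooth_timecourses,
    )
    return CellResult(cell_id, masks, profiles, L, edge, threshold, junction_x)


def _pair_signals(e: EdgeSeries, pair: str) -> tuple[np.ndarray, np.ndarray]:
    chan = {
        "Velocity": e.velocity_um_per_min,
        "Position": e.position_um,
        "Intensity": e.front_intensity,
    }
    first, second = pair.split("-", 1)
    return chan[first], chan[second]


def correlate_cohort(
    series: list[EdgeSeries],
    pairs: tuple[str, ...] = CANONICAL_PAIRS,
    window_min: tuple[float, float] = ANALYSIS_WINDOW_MIN,
    max_lag_min: float = DEFAULT_MAX_LAG_MIN,
    zero_tolerance_min: float = 0.0,
    only_qualified: bool = True,
) -> dict:
    """CC curves, peak table and lag-count ratios for a cohort.

    Time courses are restricted to the analysis window around stimulation
    (default -5 .. +30 min) before correlating.  Returns a dict with the
    per-cell ``CCResult`` lists, the peak table, the ``LagSummary`` per
    pair, and the inferred event order.
    """
    used = [e for e in series if e.qualified or not only_qualified]
    if not used:
        raise ValueError("no qualified cells")
    results: dict[str, list[CCResult]] = {p: [] for p in pairs}
    for e in used:
        sel = (e.times_min >= window_min[0]) & (e.times_min <= window_min[1])
        dt = float(np.diff(e.times_min[sel]).mean())
        for pair in pairs:
            a, b = _pair_signals(e, pair)
            results[pair].append(
                cross_correlation(
                    a[sel], b[sel], dt, max_lag_min, pair_label=pair, cell_id=e.cell_id
                )
            )
    summaries: dict[str, LagSummary] = {}
    peak_rows = []
    for pair in pairs:
        signs = []
        for r in results[pair]:
            signs.append(lag_sign(r.peak_lag_min, zero_tolerance_min))
            peak_rows.append(
                {
                    "cell_id": r.cell_id,
                    "pair": pair,
                    "peak_lag_min": r.peak_lag_min,
                    "peak_value": r.peak_value,
                }
            )
        summaries[pair] = population_lag_ratio(signs, pair)
    return {
        "cc_results": results,
        "peaks": pd.DataFrame(peak_rows),
        "summaries": summaries,
        "event_order": infer_event_order(summaries),
        "n_cells": len(used),
    }


# ---------------------------------------------------------------------------
# file-based pipeline
# ---------------------------------------------------------------------------


def load_cell_config(entry: dict, base_dir: Path) -> tuple[FrameStack, dict]:
    """Read one per-cell YAML entry and its TIFF stack."""
    path = Path(entry["tiff_path"])
    if not path.is_absolute():
        path = base_dir / path
    frames = tifffile.imread(path)
    if frames.ndim == 2:
        frames = frames[None]
    stack = FrameStack(
        frames=frames.astype(float),
        pixel_size=float(entry["pixel_size_um"]),
        frame_interval=float(entry["frame_interval_min"]),
        stim_frame=int(entry["stim_frame"]),
        channel_label=str(entry.get("channel_label", "")),
    )
    opts = {
        "rotation_deg": float(entry.get("rotation_deg", 0.0)),
        "junction_side": entry.get("junction_side", "left"),
        "threshold_override": entry.get("threshold_override"),
        "probe_label": entry.get("probe_label", "other"),
    }
    bg = entry.get("background_region")
    if bg is not None:
        x0, y0, x1, y1 = (int(v) for v in bg)
        opts["background_region"] = BackgroundRegion.from_rectangle(
            stack.shape, x0, y0, x1, y1
        )
    return stack, opts


def write_cell_outputs(res: CellResult, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    masks8 = np.stack([m.mask for m in res.masks]).astype(np.uint8) * 255
    tifffile.imwrite(out_dir / f"{res.cell_id}_masks.tif", masks8)
    brows = []
    for m in res.masks:
        bd = extract_boundary(m)
        for i, (x, y) in enumerate(bd.points):
            brows.append((m.frame_index, i, x, y))
    pd.DataFrame(
        brows, columns=["frame", "vertex_index", "x_px", "y_px"]
    ).to_csv(out_dir / f"{res.cell_id}_boundaries.csv", index=False)
    prows = []
    for f, p in enumerate(res.profiles):
        for x, v in zip(p.x_norm, p.intensity):
            prows.append((res.cell_id, f, p.time_min, x, v))
    pd.DataFrame(
        prows, columns=["cell_id", "frame", "time_min", "x_norm", "intensity"]
    ).to_csv(out_dir / f"{res.cell_id}_profiles.csv", index=False)
    res.edge.to_frame().to_csv(out_dir / f"{res.cell_id}_edges.csv", index=False)


def plot_landscape(L: Landscape, path: Path, title: str = "") -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    pcm = ax.pcolormesh(L.x_norm, L.times_min, L.values, shading="auto")
    ax.axhline(0.0, color="red", lw=1)
    ax.set_xlabel("normalized distance to junction")
    ax.set_ylabel("time (min)")
    ax.set_title(title or L.cell_id)
    fig.colorbar(pcm, ax=ax, label="normalized intensity")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_lag_ratios(summaries: dict[str, LagSummary], path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    labels = list(summaries)
    ratios = [summaries[k].ratio for k in labels]
    shown = [r if np.isfinite(r) else 0 for r in ratios]
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.bar(labels, shown, color="steelblue")
    ax.axhline(1.0, color="k", ls="--", lw=1)
    for i, r in enumerate(ratios):
        if not np.isfinite(r):
            ax.text(i, 0.1, "inf", ha="center")
    ax.set_ylabel("positive / negative lag-count ratio")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def run_pipeline(config: dict | str | Path, out_dir: str | Path, force: bool = False) -> dict:
    """Execute the full cohort pipeline from a config mapping or YAML path.

    Per-cell failures are logged and skipped; the run aborts only when no
    cell succeeds.  Returns (and writes) the manifest: successes, failures,
    effective parameters, software version.
    """
    if isinstance(config, (str, Path)):
        cfg_path = Path(config)
        with open(cfg_path) as fh:
            config = yaml.safe_load(fh)
        base_dir = cfg_path.parent
    else:
        base_dir = Path(".")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    params = {
        "grid_size": int(config.get("grid_size", DEFAULT_GRID_SIZE)),
        "front_fraction": float(config.get("front_fraction", 0.10)),
        "max_lag_min": float(config.get("max_lag_min", DEFAULT_MAX_LAG_MIN)),
        "window_min": list(config.get("window_min", ANALYSIS_WINDOW_MIN)),
        "min_extension_um": float(config.get("min_extension_um", 2.0)),
        "zero_tolerance_min": float(config.get("zero_tolerance_min", 0.0)),
    }
    successes, failures, results = [], [], []
    for entry in config["cells"]:
        cell_id = str(entry.get("cell_id", Path(str(entry["tiff_path"])).stem))
        try:
            stack, opts = load_cell_config(entry, base_dir)
            res = quantify_stack(
                stack,
                cell_id=cell_id,
                grid_size=params["grid_size"],
                front_fraction=params["front_fraction"],
                **opts,
            )
            write_cell_outputs(res, out_dir / "cells")
            results.append(res)
            successes.append(cell_id)
        except Exception as exc:  # per-cell fault isolation
            logger.error("cell %s failed: %s", cell_id, exc)
            failures.append({"cell_id": cell_id, "error": str(exc)})
    if not results:
        raise RuntimeError("zero successful cells")

    # population landscape on the common time grid
    landscapes = [r.landscape for r in results]
    t0 = max(L.times_min[0] for L in landscapes)
    t1 = min(L.times_min[-1] for L in landscapes)
    dt = min(float(np.diff(L.times_min).min()) for L in landscapes)
    times_out = np.arange(t0, t1 + 1e-9, dt)
    points = resample_to_common_grid(landscapes, times_out)
    pop = average_surface(points, landscapes[0].x_norm)
    pop.surface.to_frame().to_csv(out_dir / "population_landscape.csv", index=False)
    plot_landscape(pop.surface, out_dir / "population_landscape.png", "population average")
    try:
        norm = normalize_by_prestimulus(pop.surface)
        norm.to_frame().to_csv(out_dir / "population_landscape_normalized.csv", index=False)
        plot_landscape(norm, out_dir / "population_landscape_normalized.png",
                       "pre-stimulus normalized")
    except ValueError as exc:
        logger.warning("pre-stimulus normalization skipped: %s", exc)

    # cross-correlation analysis
    cc = correlate_cohort(
        [r.edge for r in results],
        max_lag_min=params["max_lag_min"],
        window_min=tuple(params["window_min"]),
        zero_tolerance_min=params["zero_tolerance_min"],
    )
    curves = []
    for pair, lst in cc["cc_results"].items():
        for r in lst:
            for lag, v in zip(r.lags_min, r.cc):
                curves.append((r.cell_id, pair, lag, v))
    pd.DataFrame(curves, columns=["cell_id", "pair", "lag_min", "cc"]).to_csv(
        out_dir / "cc_curves.csv", index=False
    )
    cc["peaks"].to_csv(out_dir / "cc_peaks.csv", index=False)
    summary_json = {
        pair: {
            "n_positive": s.n_positive,
            "n_negative": s.n_negative,
            "n_zero": s.n_zero,
            "ratio": s.ratio if np.isfinite(s.ratio) else "inf",
        }
        for pair, s in cc["summaries"].items()
    }
    with open(out_dir / "lag_summary.json", "w") as fh:
        json.dump({"pairs": summary_json, "event_order": cc["event_order"]}, fh,
                  indent=2, default=str)
    plot_lag_ratios(cc["summaries"], out_dir / "lag_ratios.png")

    manifest = {
        "version": __version__,
        "parameters": params,
        "successes": successes,
        "failures": failures,
        "n_cells": len(successes),
        "outputs": sorted(p.name for p in out_dir.iterdir()),
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
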