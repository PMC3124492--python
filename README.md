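# stripquant

Quantification of polarized biosensor activity in single cells confined on
1-D micropatterned strips.

## The problem

When a fibroblast adheres to a fibronectin strip with a stable cell–cell
junction at one end and a free end capable of lamellipodial protrusion at
the other, the subcellular distribution of a fluorescent activity probe
(e.g. a PH-Akt-GFP reporter of PI3K activity, or a PAK-PBD reporter of
active Rac1) can be quantified as a function of the distance to the
junction. Upon uniform growth-factor stimulation these cells polarize: the
probe accumulates at the free end while the edge extends. `stripquant`
turns time-lapse movies of such cells into:

- **normalized intensity profiles** — per frame, the y-averaged intensity
  inside the cell mask plotted against the normalized distance to the
  junction x ∈ [0, 1], with cell length and total intensity both
  normalized to unity so cells of different size and expression level are
  comparable;
- **spatiotemporal activity landscapes** — profiles stacked along time,
  per cell and averaged over a population (robust locally weighted
  quadratic regression through all cells' points at each time), and
  normalized by the pre-stimulation curve to remove time-constant
  morphology and perinuclear bias;
- **free-end edge dynamics** — edge position (distance of the furthest
  mask pixel from the junction, in µm), edge velocity (central
  difference), and the maximal probe intensity in the distal 10% of cell
  length;
- **cross-correlation lag analysis** — for signals A and B, the Pearson
  correlation of {A(t), B(t+τ)} over the overlap for every frame lag τ. A
  peak at positive lag means A occurs earlier than B. Per cell-population
  pair, the ratio of cells with positive versus negative peak lags orders
  the events: edge-extension initiation (velocity), stable extension
  (position), probe activation (front intensity).

Only cells whose free end extends by more than 2 µm after stimulation
enter the correlation analysis. Time courses from −5 to +30 min around
stimulation are used, smoothed by robust loess with a 20-min window;
spatial profiles use a window of 10% of cell length and mask boundaries a
3-pixel window. Segmentation uses Otsu's threshold (one threshold per
sequence, user-overridable), keeping the largest 4-connected component
with holes filled.

Because raw strip-cell movies of this kind are generally not publicly
deposited, the package ships a first-class synthetic-movie generator
(`stripquant.synthetic`) that renders ground-truthed strip cells — a
scripted free-end trajectory, a polarized body profile with a perinuclear
bump, a front bump whose amplitude follows the edge dynamics at a
programmable frame lag, constant background, and additive noise — so every
pipeline stage is testable against what was written.

## Worked example

```python
import numpy as np
from stripquant import (SimSpec, simulate_cell_movie, quantify_stack,
                        BackgroundRegion, correlate_cohort, simulate_cohort)

spec = SimSpec(seed=0)                      # one PI3K-like synthetic cell
stack, truth = simulate_cell_movie(spec)
res = quantify_stack(stack, cell_id="demo",
                     background_region=BackgroundRegion.from_rectangle(
                         stack.shape, 0, 0, 10, 10))
print(f"threshold: {res.threshold:.1f}  junction column: {res.junction_x:.0f}")
print(f"edge extension after stimulation: "
      f"{res.edge.position_um[-1] - res.edge.position_um[spec.stim_frame]:.2f} um")
print(f"qualified for CC analysis: {res.edge.qualified}")

series = [quantify_stack(st, cell_id=f"c{i}",
          background_region=BackgroundRegion.from_rectangle(st.shape, 0, 0, 10, 10)).edge
          for i, (sp, st, tr) in enumerate(simulate_cohort(6, seed=0))]
cc = correlate_cohort(series)
for pair, s in cc["summaries"].items():
    print(f"{pair}: +{s.n_positive}/-{s.n_negative}  ratio {s.ratio}")
print("event order:", " -> ".join(cc["event_order"]["order"]))
```

prints

```
threshold: 21.4  junction column: 11
edge extension after stimulation: 5.12 um
qualified for CC analysis: True
Velocity-Intensity: +6/-0  ratio inf
Position-Intensity: +0/-6  ratio 0.0
Position-Velocity: +0/-6  ratio 0.0
event order: extension initiation (velocity) -> probe activation (intensity) -> stable extension (position)
```

The Otsu threshold (21.4) separates the ~200-count cell from the
background after subtraction; the cell extends 5.1 µm after stimulation
and so passes the 2-µm inclusion filter. In all six simulated cells the
Velocity–Intensity peak lag is positive (velocity leads the probe, whose
bump was programmed to follow velocity by 2 frames) and the
Position–Velocity lag negative (initiation precedes stable extension) —
so the inferred event order is velocity → probe → position.

## Command line

```
stripquant simulate  --preset polarizing --n-cells 5 --seed 1 --out data/
stripquant run       --config data/cells.yaml --out results/
stripquant quantify  --config data/cells.yaml --out results/cells
stripquant landscape --profiles results/cells --average --normalize --out results/
stripquant correlate --edges results/cells --window -5:30 --max-lag 15 --out results/
```

`run` executes the whole chain and writes per-cell masks (8-bit TIFF),
boundary/profile/edge CSVs, the population landscape (raw and
pre-stimulus-normalized, CSV + PNG), CC curves and peak tables, the
lag-count summary JSON, and a `manifest.json` echoing every effective
parameter. Per-cell failures are logged and skipped without aborting the
cohort.

Per-cell YAML entries: `tiff_path`, `pixel_size_um`, `frame_interval_min`,
`stim_frame`, `rotation_deg`, `junction_side` (left|right),
`background_region` ([x0, y0, x1, y1]), optional `threshold_override`.

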