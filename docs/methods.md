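# Methods

## Pipeline model and assumptions

A cell confined to a micropatterned strip is treated as a quasi-1-D
object: after rotation the strip axis is horizontal, the junction end is
the leftmost extent of the cell mask and the free end the rightmost. All
spatial quantification reduces to functions of the x-coordinate. The
method assumes one cell per strip, a stationary junction, and a
fluorescence signal whose y-averaged, length- and intensity-normalized
profile is a meaningful readout of probe activity (i.e. expression level
and focus shifts act as overall scale factors, which the unit-sum
normalization removes).

### Preprocessing

Each frame is median-filtered (3×3, borders by edge replication).
Background is the mean intensity over a fixed, cell-free region — a single
region outline serves the entire sequence, so background-subtracted
frames never need to be stored — subtracted per frame with negative
values clipped to zero (profiles are later normalized by total intensity;
negative values would break that contract). Frames are rotated (bilinear,
canvas grows to preserve content) and mirrored when the junction lies to
the right, so the free end always points toward +x.

Segmentation uses a single threshold for the whole sequence: Otsu's
method (256 histogram bins over the observed min–max) computed on the
first pre-stimulation frame, or a per-sequence user override. Pixels at or
above the threshold are binarized; only the largest 4-connected component
is kept (neighboring cells and noise specks would otherwise corrupt the
mask) and fully enclosed holes are filled — filled hole pixels may fall
below the threshold, which we accept as the cost of a simply connected
mask. The boundary is the sub-pixel 0.5-level contour of the
(zero-padded) mask, with each coordinate channel smoothed by a degree-1
locally weighted fit over a 3-pixel window, applied periodically around
the closed contour.

### The shared smoother

One smoother serves the whole pipeline: locally weighted polynomial
regression with tricube distance weights and optional bisquare
robustness. At each evaluation point a degree-1 or degree-2 polynomial is
fitted to the samples inside the window (fraction of the x-range, or
absolute width in x-units); with robustness on, the fit is iterated twice
with bisquare weights that zero out samples whose residuals exceed six
times the median absolute residual. Its three contracted uses:

| use | degree | robust | window |
| --- | --- | --- | --- |
| mask boundary coordinates | 1 | no | 3 pixels (absolute, contour index) |
| spatial intensity profiles | 2 | yes (2 iters) | 10% of cell length |
| edge/intensity time courses | 2 | yes (2 iters) | 20 min (absolute) |

Numerical choices: windows holding fewer than degree+2 points (series
ends) expand to the nearest degree+2 samples; a window too narrow to hold
degree+2 points anywhere raises an error. The bisquare scale is floored
at 10⁻³ of the data range: on (near-)noiseless data the median absolute
residual reflects lack-of-fit rather than outliers, and an unfloored
scale makes the reweighted fit numerically unstable (this floor is what
makes smoothing exactly invariant under duplicating the input points).
Robustness iterations are fixed at two.

### Profiles and landscapes

The raw profile is the per-column mean of in-mask intensities. It is
mapped linearly so the junction column lands at 0 and the free-end column
at 1, resampled onto a fixed uniform grid of G = 101 points (1%
resolution, comfortably finer than the 10% smoothing window;
configurable), and divided by its sum. After loess smoothing, negatives
are clipped and the profile renormalized, so every profile obeys
sum = 1 within 1e−9. The junction is taken as the leftmost mask column
over the whole sequence (the junction is stationary; using the global
minimum makes it a valid lower bound for every frame despite
segmentation noise).

A landscape stacks one cell's profiles by time. For population averages,
each cell's landscape is first linearly interpolated in time onto a
common time grid — cells never extrapolate beyond their observed range;
they simply drop out of times they do not cover. At each common time a
robust degree-2 loess (window 10% of the x-range) is fitted through the
pooled points of all contributing cells and evaluated on the grid; rows
are clipped at zero and renormalized, so the population surface satisfies
the same unit-sum contract as single cells and the n = 1 case reduces
exactly to the single cell's smoothed landscape. Weighting is per point,
not per cell; resampling all cells to the common grid first keeps this
from systematically favoring densely sampled cells.

Pre-stimulus normalization divides every row by the mean of all rows with
t < 0 (the mean is more robust than a single reference frame and reduces
to it when only one pre-stimulus frame exists). Grid points where the
reference falls below 1% of its maximum are masked as undefined rather
than amplified. By construction the operation is gauge-invariant:
multiplying the whole landscape by any time-constant spatial function —
cell morphology, perinuclear probe trapping — cancels exactly.

Two-channel ratio images divide the channels pixelwise inside the mask,
with pixels whose denominator falls below 1% of its in-mask median set
undefined (NaN), never infinite.

### Edge dynamics and cross-correlation

Edge position is (max mask column − junction column) × pixel size;
velocity is the central difference (one-sided at the ends; forward and
backward schemes are available as the robustness control — on smooth
trajectories the choice never flips the downstream lag sign). Front
intensity is the maximum of the normalized profile over
x ∈ [0.9, 1]. Position is smoothed, differentiated, and the velocity
smoothed again (smoothing before differencing suppresses pixel-quantized
jumps; the reverse order is available through the unsmoothed path). Cells
whose raw position never exceeds its stimulation-frame value by more than
2 µm after stimulation are excluded from correlation analysis.

The CC curve evaluates, for every integer-frame lag within ±15 min
(default; necessarily below half the 35-min analysis window), the Pearson
correlation of the overlapping samples, with mean and SD computed on the
overlap so the estimate is a true correlation at every lag. Lags with
fewer than 8 overlapping samples or zero variance are undefined and
excluded from the peak search. The peak is the most positive correlation
(both probes are assumed to positively regulate extension; troughs are
ignored), ties broken toward the smallest |lag| and then toward positive.
Positive peak lag ⇒ the first signal precedes the second. Per pair, cells
are counted by lag sign; zero-lag cells are excluded from the
positive/negative ratio (reported as inf when no negative-lag cells
exist). Ratios > 1 define precedence edges over {velocity, position,
intensity}; a topological sort yields the event order, and cyclic edge
sets are reported as inconsistent rather than resolved. Time courses are
not detrended beyond loess smoothing.

## Synthetic data: what it emulates, and what it does not

The generator renders the regime the pipeline targets: a 60×220-px field
at 0.39 µm/px (3 px ≈ 1.17 µm, a 40× objective), 36 one-minute frames
with stimulation at frame 5 so the movie spans exactly the −5…+30 min
analysis window; a strip-band cell of baseline length 50 µm from a fixed
junction column; body intensity ~200 counts with a perinuclear Gaussian
bump (amplitude 150 at x_norm = 0.3); a front Gaussian bump just behind
the edge whose amplitude follows the positive part of the edge velocity
(or position) delayed by a programmable lag (default +2 frames, gain
150); constant background 20; additive Gaussian noise (SD 10 by default;
Poisson optional). Edge trajectories are sigmoid (default: 5 µm amplitude,
onset 2 min post-stimulus), ramp, or oscillatory. Cohorts draw per-cell
jitter (±20% amplitude and rate, ±1.5 min onset, ±10% length) from
per-cell RNG streams seeded by (seed, cell index), so cohorts are
reproducible and order-independent.

Not emulated: optical blur (no PSF convolution), photobleaching, focus
drift, ruffle texture, neighboring cells, or reaction–diffusion biosensor
kinetics. Passing tests therefore demonstrate that the pipeline recovers
what the generator wrote under realistic intensity statistics and
geometry — not that segmentation or lag estimates are unbiased under
every optical artifact of real microscopy.

## Parameters that matter

| parameter | default | units | rationale |
| --- | --- | --- | --- |
| grid size G | 101 | points | 1% spatial resolution, below the 10% window |
| spatial smoothing window | 0.10 | fraction of cell length | noise suppression vs landscape detail |
| boundary smoothing window | 3 | px | sub-pixel contour jitter removal |
| time smoothing window | 20 | min | slower than protrusion cycles, faster than the response |
| analysis window | −5…+30 | min | pre-stimulus baseline must enter the CC |
| max CC lag | ±15 | min | < half the analysis window |
| min overlap per lag | 8 | samples | correlation estimates below this are noise |
| inclusion threshold | >2 | µm extension | excludes non-responding cells |
| front region | 10% | of cell length | distal band where protrusive signaling concentrates |
| division guards | 1% | of reference max / in-mask median | avoid amplifying near-zero denominators |

## Problem sizes

The test suite and the acceptance script run cohorts of up to 20
simulated cells of 36 frames at 60×220 px — desk-scale sizes at which the
full chain (rendering, segmentation, profiling, averaging, correlation)
completes in about a minute while leaving every statistical property
(lag-ratio recovery, 3-SE average consistency, ≥90% sign agreement)
testable.

## Known limitations

- The junction coordinate is inferred from the mask (global leftmost
  column) rather than tracked; a drifting junction would bias positions.
- Per-point weighting in the population average favors cells contributing
  more points when cells are unevenly sampled in x.
- The peak search considers only positive-correlation peaks; inhibitory
  probes (negative regulation) would need the trough convention.
- Zero-lag handling in the lag-count ratio (exclusion from both counts)
  is a convention; with coarse sampling many cells can land at lag 0.
- The rloess-style smoother evaluates windows by x-distance, not by
  nearest-neighbor span; for strongly non-uniform sampling the two
  conventions differ near gaps.
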