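# Methods

`micropat` quantifies how a fluorescence signal is distributed across a
circular micropatterned island of cells. The motivating biology is the
spatial organization of tumor-cell islands: mitochondrial membrane
potential (ΔΨm, reported by TMRM intensity) and adherens-junction markers
(E-cadherin) vary systematically between the island center and its edge,
and the package turns single-channel micrographs of such islands into
radial profiles, region means, fold changes and per-cell junction metrics.

## Coordinate frame and the normalized radius

All image operations use pixel-center coordinates: origin at the top-left
pixel center, x rightward (columns), y downward (rows), 0-based.

The island is represented by an `IslandROI`: a centroid plus a boundary,
either a circle (radius in px) or a simple polygon. Every pixel inside the
boundary is mapped to normalized polar coordinates

- θ = atan2(y − cy, x − cx), in [−π, π)
- r = d / R(θ)

where d is the Euclidean distance to the centroid and R(θ) is the distance
from the centroid to the boundary *along the same direction* — constant for
a circle, an exact ray/edge intersection for a polygon. This makes r = 1
the true island edge in every direction even for hand-drawn, imperfectly
circular ROIs; a single scalar radius would misplace edge pixels of an
elongated island. On a square island, both the edge midpoint and the
corner map to r = 1 (R(θ) along the diagonal is √2 × half-side), which the
tests verify analytically.

## Island detection

Auto-detection smooths the image (Gaussian, σ = 2 px by default — enough
to suppress single-pixel noise without materially moving a hard edge),
applies Otsu's threshold, keeps the largest connected foreground component,
and fills holes. The centroid is the unweighted centroid of the filled
mask. If the mask circularity 4πA/P² (Crofton perimeter) is ≥ 0.85 the
boundary is stored as a circle of equivalent-area radius √(A/π); otherwise
as the traced, simplified mask outline.

A user-supplied (manual) ROI always overrides detection. This mirrors the
original hand-drawn-ROI workflow and matters in practice: a single global
threshold cannot reliably keep a dim island rim attached to a much brighter
core. On a synthetic center-high island (core ≈ 400 counts, rim ≈ 133,
background 10) Otsu segments the bright core and the detected radius is
~35% too small. This is an intrinsic limitation of single-threshold
detection on effectively trimodal intensity histograms, so quantitative
experiments on center-high patterns use the manual ROI path; detection is
validated on flat and edge-high islands, where it recovers a planted disc
centroid within 0.5 px and its radius within 1%.

## Radial profile

Pixels are binned by r into `n_bins` equal-width, half-open bins over
[0, 1] (the last bin closed); per bin the mean, population SD and pixel
count are reported. Empty bins carry NaN, never an imputed value. The
default of 50 bins gives smooth curves at the 512×512 desk scale and is a
config key. "Normalized" plots divide the mean curve by its maximum
(`normalization="max"`); division by the pixel-weighted grand mean
(`"mean"`) and raw output are also provided, since published radial
distribution plots rarely state their normalization.

## Center/edge region quantification and fold change

Mirroring the manual 5-ROI protocol, `place_region_rois` puts n (default
5) axis-aligned squares per region: center ROIs on a small circle at
r = 0.1 (on the centroid itself when n = 1), edge ROIs equally spaced in
angle at r = 0.85, with side 0.1·R(θ) (all config keys: `center_r`,
`edge_r`, `n_rois`, `roi_side`, `start_angle`). These placement values are
explicit stand-ins: published figures show the ROIs pictorially but do not
parameterize them. A square that would cross the boundary raises a
placement error rather than silently clipping.

The fold change is (edge_mean − b) / (center_mean − b) with a single
scalar background b per image — 0 by default, or the median intensity
outside the island boundary when `background_mode: median_outside` is set.
Background subtraction is an explicit, logged option rather than hidden
preprocessing.

## Contact index

For two traced cell contours A and B the contact index is
area(A∩B)/area(A∪B), computed by exact polygon clipping (shapely/GEOS).
Exact geometry removes raster-resolution dependence; a brute-force oracle
(masks scan-converted at 0.01 px pitch) ties the value back to the raster
definition in tests, agreeing to ~4·10⁻⁴ on random convex pairs. Because
GEOS results are not bit-identical under operand swap, operands are
ordered canonically inside the function so index(a, b) == index(b, a)
exactly. For congruent shapes with pairwise overlap fraction f the index
is f/(2 − f), which the fixture factory `generate_contour_pair` returns in
closed form.

## Cell counting

ITCN-style: band-pass with a difference of Gaussians (σ = d/4 and d for
expected cell diameter d), then greedy selection of local maxima above a
data-relative threshold (mean + k·SD of the filtered interior, k = 2 by
default) with minimum separation d/2. Candidates are processed in
decreasing filtered intensity; ties break toward the smallest (y, x), so
the result is deterministic. The relative threshold makes the count
invariant to global intensity rescaling. On 50 planted Gaussian blobs
(σ = 4 px, separation ≥ 16 px) at Poisson peak SNR ≥ 10 the counter
achieves 100% recall with 0 false positives at the fixed test seed; the
acceptance thresholds are ≥ 95% and ≤ 5%. Density is count per ROI area —
cells/mm² when the image carries a pixel size, else cells/px².

## Line scans

A scan samples `n_samples` points uniformly along a user-supplied segment;
at each point the intensity is the mean of `width` bilinear sub-samples
spaced 1 px apart perpendicular to the segment. The segment midpoint
defines position 0 (the junction); automatic junction detection is out of
scope — segments come from the user or from synthetic ground truth.
`average_line_scans` aligns scans by position and reports position-wise
mean and SD, as in published multi-pair junction averages.

## Junction area per cell

The marker channel is binarized (Otsu computed within the union of the
cell contours, or a fixed threshold), and each cell's junction area is the
count of above-threshold pixels within a band of half-width 2 px (config
key) around its polygon boundary. The band restricts the measurement to
membrane-localized signal; whole-cell thresholding would count cytoplasmic
staining. An all-background threshold result produces zeros with a warning,
not an error. The published quantity "junction-marker area per cell" is
not defined precisely in the source workflows; the boundary-band
construction is this package's explicit stand-in.

## Synthetic data generator

`generate(SyntheticSpec)` renders, in fixed order with all randomness from
one `numpy` generator seeded by `spec.seed`:

1. background + island·I(r) for a chosen radial model — flat, linear,
   edge-high sigmoid lo + (hi−lo)/(1+e^(−k(r−r0))), center-high sigmoid,
   or step;
2. cell centers rejection-sampled uniformly in the island with a minimum
   separation (packing failure after 1000·n attempts raises an error);
3. isotropic Gaussian blobs at the centers;
4. optionally, Gaussian-cross-section ridges along the shared edges of the
   bounded Voronoi tessellation of the centers clipped to the island — a
   cobblestone-like monolayer junction geometry without any biophysical
   cell model;
5. Poisson resampling (shot noise), then additive Gaussian read noise,
   then clipping and rounding to the bit depth.

Identical spec + seed gives a bit-identical image; the paired
`GroundTruth` carries the island ROI, model parameters, cell centers,
tessellation contours, junction segments and the planted fold change
I(edge_r)/I(center_r).

Defaults are chosen as realistic desk-scale study conditions: 512×512 px
frame, island radius 200 px (a scaled stand-in for 500 µm–2 mm patterns),
edge-high sigmoid with peak 400 counts — Poisson-limited peak SNR
√400 = 20, a typical widefield regime — and an edge:center contrast close
to 3, the magnitude reported for ΔΨm gradients across confined tumor
islands. Camera background offset defaults to 10 counts.

What the generator does **not** emulate: optical blur/PSF, uneven
illumination, out-of-focus haze, autofluorescence texture, cell-shape
irregularity beyond Voronoi polygons, or any signaling/physiology. Passing
recovery tests therefore demonstrates correctness of the measurement
chain under the stated noise model, not robustness to every real-world
artifact; on real data the manual-ROI and config pathways exist precisely
to absorb those differences.

## Pipeline and reproducibility

`run(RunConfig)` executes requested stages (profile, regions, contact,
count, linescan, junction_area) in order, writing one CSV per stage and a
JSON manifest with the full config, its SHA-256 hash, package version,
input checksums and output paths. Timings go to the log, never into data
files, so repeated runs are byte-identical and a manifest's recorded
config reproduces its outputs. Floats are serialized with 9 significant
digits. Statistical testing (t-tests/ANOVA) is deliberately excluded;
`compare_conditions` stacks per-island metrics into a tidy long table
ready for external statistics tools.

## Problem sizes and numerical choices

Validation experiments run at 512×512 px (≈126k island pixels), 50 radial
bins, 50 planted cells, 200 random polygon pairs for the contact-index
oracle, and 20 junctions per line-scan average. Tolerances: flat-field
and rotation invariances at 1e−9 (pure float arithmetic), planted-model
profile recovery at 1% noise-free and 2% RMSE of dynamic range under peak
SNR 20, fold-change recovery within [2.7, 3.3] of a planted 3.0, contact
index vs raster oracle within 0.01 absolute. Degenerate inputs (all-zero
images, zero-area polygons, empty sampling squares, infeasible packings)
raise typed errors rather than producing silent zeros, with the single
documented exception of an empty junction-marker foreground, which warns
and reports zero areas.
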