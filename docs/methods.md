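# Methods

This note documents the models, conventions and numerical choices in
`octava`, in the order the pipeline applies them, and states what the
built-in phantoms do and do not establish.

## Image model and pre-processing

An angiogram is a 2-D raster of intensities normalized to [0, 1] with
an isotropic physical pixel size (μm/pixel) supplied by the user; all
lengths and diameters derive from that scale. 8- and 16-bit grayscale
TIFF/PNG are accepted and divided by the container's full scale; RGB
files are accepted only when all color channels are identical.

A circular region of interest is implemented as a bounding-box crop
plus an *exclusion mask* rather than zero-filling: excluded pixels
count toward neither vessel area nor total area, so density
denominators remain unbiased (zero-filling would deflate VAD by the
corner area). Rescaling is bilinear; the pixel size is divided by the
factor so physical extent is preserved to within one output pixel.
The median filter uses replicated borders; kernel 1 is the identity.
The default median kernel is 3; for strongly speckled images a larger
kernel (5–7) is appropriate, and the phantom-recovery tests use 7 on
the speckled phantom.

## Vessel enhancement

The multiscale Frangi vesselness filter (bright ridges on dark
background) is computed at Gaussian scales on a geometric ladder from
σ_min (default 1 px) to σ_max (default 7 px), one scale per integer
of σ_max by default, with anisotropy sensitivity β = 0.5 and
structureness cutoff c equal to half the maximum Hessian norm per
scale — the original-publication conventions. The per-pixel maximum
over scales is min–max normalized to [0, 1] globally (not per scale),
since the downstream thresholds are histogram-based. Reflect padding
avoids spurious edge ridges. Enhancement output is invariant to affine
rescaling of the input intensities.

σ_max is the operative tuning knob: it should reach about half the
largest vessel width in pixels. In the supported range σ_max ∈ [1, 8]
the response full-width-at-half-maximum of a bar stays within +2 px of
the bar width (no gross dilation) — a property test enforces this.
Images whose vessel widths span a very large range (such as the
two-width channel grid) are better segmented *without* enhancement: a
single scale band cannot serve 12-px and 75-px channels at once, so
the pipeline exposes enhancement as an optional stage.

## Segmentation

All histogram-shape thresholds quantize intensities to 256 levels
regardless of input bit depth, which makes thresholds reproducible
across 8- and 16-bit sources; a pixel exactly at a threshold is
foreground everywhere.

* **fuzzy** (default): exhaustive search over the 256-bin histogram
  for the split minimizing the Huang–Wang entropy of fuzziness, with
  membership u(g) = 1/(1 + |g − μ_side|/C) and Shannon entropy
  −u ln u − (1−u) ln(1−u). Ties resolve to the lowest level.
* **adaptive**: foreground iff intensity > local mean − offset
  (default kernel ≈ image width/8, odd; offset 0). On noisy but
  uniform regions it marks ≈ half the pixels — it is included as a
  comparison baseline, not a recommendation.
* **global-mean**: threshold at the mean intensity; also the reference
  convention when scoring segmenters against a known-geometry image.
* **isodata**: Ridler–Calvard intermeans iteration to its fixed point.
* **kmeans**: two-cluster 1-D Lloyd with centroids initialized at the
  min/max levels (deterministic); vessel = brighter cluster.

A constant image has no threshold and raises a degenerate-input error;
the pipeline converts this into a report whose metrics are recorded as
missing-with-reason.

## Skeleton, thickness and network topology

The mask is thinned with a topology-preserving medial-axis algorithm
(Lee-type, 2-D). Thinning of a wide ribbon clipped at the image border
retracts the centerline by about half the ribbon width at that end;
this is the dominant (few percent) deficit of measured vessel length
density on phantoms.

Local thickness follows the largest-inscribed-disk definition:
thickness(p) = 2·max{r : p lies inside a disk of radius r fully
contained in the foreground}. It is evaluated by sweeping radii
downward (quantized at 0.5 px): the pixels with thickness ≥ 2r are the
dilation by radius r of the set with Euclidean distance transform
≥ r, and the dilation itself is evaluated with a second distance
transform. On pixel rasters a ribbon of odd pixel width w measures
w + 1 px (distances run between pixel centers); all thickness-based
assertions therefore carry a ±1 px tolerance.

Nodes are centerline pixels whose 8-neighbor ring contains ≥ 3
connected foreground runs (the crossing number), clustered by
8-adjacency into single nodes with centroid coordinates. Counting
runs, rather than raw neighbors, avoids false junctions at diagonal
corners and at pixels flanking a genuine crossing. After removing node
pixels, the remaining arcs are traced into ordered paths (orthogonal
steps preferred at square corners so corner pixels are not stranded;
diagonal adjacencies that pass through a junction pixel are severed).
Arcs attached to nodes at both ends are *segments*, at one end
*branches*, at neither *isolated*; attached arc ends are extended by
the adjacent junction pixel so arc lengths span node to node. An
element touching the image border is classified normally — the border
end counts as free. Isolated elements whose maximum local diameter is
below the *twig size* (default 3 px) are excluded as probable noise
and audited. Mesh regions are 4-connected background components of
the skeleton raster touching no border (4-connectivity for background
against 8-connectivity for foreground keeps Jordan-curve
consistency).

Junction bulges would inflate diameters, so centerline pixels within a
node's own local-thickness radius of the node centroid are excluded
from diameter averaging (elements keep their full paths for length
metrics; an element whose pixels are all excluded reports a missing
diameter).

### Arc length

Arc length sums Euclidean steps along the centerline path after a
5-point moving-average smoothing with pinned endpoints. On straight
chains the smoothing is the identity, so axis-aligned and diagonal
paths keep the exact 1-px / √2-px step convention; on digitized curves
it removes the staircase bias, which would otherwise overestimate arc
length by up to ~8% (worst at 22.5° runs) and inflate a digitized
semicircle's tortuosity by ~15%. With smoothing the semicircle
tortuosity converges to π/2 − 1 within 0.6% at radius 120 px. Chord
length is the Euclidean endpoint distance; tortuosity = L_s/L_c − 1,
undefined (missing) for single-pixel and closed-loop elements.

## Metrics

* VAD (%) = 100 · foreground / non-excluded pixels.
* VLD (%) = 100 · skeleton pixels / non-excluded pixels (each
  centerline pixel stands for a 1-px-diameter vessel).
* Total vessel length (mm) = Σ per-element arc lengths; this uses the
  smoothed step lengths, consistent with tortuosity.
* Mean/median diameter (μm) are statistics of *per-element mean*
  diameters, not pooled pixels, matching the per-vessel reporting
  convention; histograms default to 10 μm bins (lengths 0.1 mm,
  tortuosity 0.05).
* Branchpoint density = node count / total vessel length (nodes/mm).
* Fractal dimension: box counting on the binary mask with dyadic box
  sizes s = 2, 4, …, ≤ min(H, W)/4, grid origin fixed at (0, 0) (no
  origin averaging — determinism over a marginal accuracy gain); FD is
  the least-squares slope of log N vs log(1/s) clipped to [0, 2], and
  the quoted spread is the SD of successive two-point slopes. The mask
  (not the skeleton) is used because FD measures how the *network
  fills space*; a skeleton variant can be computed by passing the
  skeleton raster.
* Connectivity factor CF = 1 − S_i/S_t over all retained linear
  elements (segments + branches + isolated).

Histogram modes (used for the bimodal channel-width readout) are
located by deterministic 1-D 2-means clustering of the samples
followed by the left edge of the most populated fixed-width bin per
cluster.

## Repeatability

For an n-subjects × m-repeats matrix: S_w = √(mean per-subject sample
variance) (ddof 1); the measurement error ME is S_w itself; CR =
2.77·S_w; 95% CI = CR ± 1.96·S_w/√(2·n·(m−1)). The radical in the CI
denominator is required to reproduce the standard Bland–Altman worked
examples at n = 8, m = 3; subjects with missing repeats are dropped
with a warning. S_w, CR and the CI scale linearly with the data
(scale equivariance) and are unchanged by additive shifts.

## Phantoms: what they emulate and what they do not

**Channel grid** (deterministic): per 1.08-mm tile, six 50-μm vertical
channels merge at right angles into one 300-μm horizontal channel,
tiled 2×2 at 4 μm/pixel, intensity 0.9 on 0.1. At 4 μm/pixel the
50-μm width rasterizes to 12 px = 48 μm, within the ±1 px tolerance
used throughout. Ground truth: raster-exact area fraction; axis
aligned centerlines; analytic lengths and widths; 24 junctions.

**Vessel network** (seeded): nine sinusoidal vessels in disjoint
horizontal bands across a 10 mm × 10 mm field at 9.3 μm/pixel, with
eight straight rungs joining adjacent vessels (two T-junctions each),
diameters uniform in 60–160 μm, per-vessel tortuosity solved from the
`sinuosity` target (default 0.15, jittered ±30%, amplitude-clamped to
the band). Vessel intensity 0.8 modulated sinusoidally along the
centerline (amplitude `intensity_variation`, default 0.3, 1-mm
period) over background 0.05; the whole image is multiplied by
unit-mean gamma speckle with SD `noise_level` (default 0.2, i.e.
SNR 5). Ground-truth lengths and tortuosities come from the
generating polylines, junction counts from the rung construction, and
only the area fraction is taken from the raster. Ground-truth
centerlines are rasterized as 8-connected chains with corner-cutting
so their pixel counts are commensurable with a thinned skeleton.

These phantoms exercise geometry, quantization, junction handling,
intensity variation and multiplicative noise. They do not emulate
depth-projection artifacts, motion artifacts (beyond the synthetic
streak helper), vessel-crossing ambiguity, spatially correlated OCT
speckle, or the contrast statistics of real tissue — passing the
phantom suite shows the measurement chain is correct on known
geometry, not that segmentation is optimal on clinical images.

Problem sizes in the test and acceptance runs are the phantom
defaults: 540×540 px (channel grid) and 1075×1075 px (network), sizes
at which every stage is exact enough for the stated tolerances while
the full suite completes in a couple of minutes.

## Validation tolerances

* Channel-grid diameter modes: nominal width ± one pixel (4 μm).
* VAD/VLD vs ground truth on noise-free phantoms: relative error
  ≤ 10% (observed: VAD exact on both; VLD ≈ 7% low on the grid from
  border-end skeleton retraction, ≈ 1% on the network phantom).
* Parameter recovery on the speckled phantom at SNR 5: per-element
  mean diameter and mean tortuosity within 10% of the generator's
  ground truth.
* Repeatability worked examples: printed-precision agreement (one
  unit in the last printed digit; one published CR value is a
  truncation rather than a rounding of the exact 2.77·S_w).

## Known limitations

* 2-D only; crossing vessels at different depths merge into junctions.
* No automated gap-filling: breaks in dim vessels stay broken unless
  manually curated, because automatic extrapolation can fabricate
  connectivity where a real occlusion exists.
* VLD inherits a small negative bias where wide vessels are clipped by
  the image border (thinning retraction).
* Local thickness and diameter histograms are quantized at one pixel;
  at 9.3 μm/pixel that is coarse relative to capillaries.
* The twig-size default (3 px) is a noise heuristic and may need
  adjustment per dataset.
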