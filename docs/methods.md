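# Methods

## The indicator

A *contour* is an extended zone of sharp reflectance gradient. The package
measures landscape structure as the density and contrast of such contours:
a managed agricultural mosaic is rich in anthropogenic boundaries (field
edges, roads, shelterbelts, settlement outlines); abandonment erodes them
while leaving mean reflectance comparatively stable. The Contour Density
Indicator (CDI) at a pixel is the mean retained gradient amplitude over a
centered sliding window. The chain is:

contrast stretch → Gaussian smoothing → Sobel/Prewitt gradient →
non-maximum suppression → morphological thinning → hysteresis selection →
window mean.

The crucial departure from a stock edge detector is that hysteresis does
not binarize: accepted edge pixels keep their gradient magnitude `G`, so
the indicator responds to boundaries *weakening*, not only to boundaries
disappearing.

### Assumptions

- Input is a single reflectance band (or a derived index such as NDVI) in
  a projected CRS in meters; all dates are co-registered on one grid.
- Landscape structure, not spectral content, is the signal of interest;
  two dates per comparison, acquired in the same phenological window.
- Cloud/shadow masks are provided externally and simply intersect the
  validity mask.

## Parameters

| parameter | default | units | rationale |
|---|---|---|---|
| contrast stretch percentiles | 2–98 | % | robust linear stretch to [0, 1]; keeps threshold levels meaningful across scenes |
| `gaussian_sigma` | 1.0 | px | noise suppression without destroying 1–2 px linear features at 10 m resolution |
| `high_threshold`, `low_threshold` | 0.9, 0.5 | quantile levels | see "Threshold semantics" below |
| window | 2000 (regional), 200 (detail) | m | regional maps aggregate whole field complexes; detail maps resolve single boundaries; both converted to the nearest odd pixel count (201 px, 21 px at 10 m) |
| `r_threshold` | 0.95 | – | stable areas must be almost perfectly locally correlated between dates |
| `corr_window_px` | 11 | px | local correlation block: large enough for a meaningful Pearson r (≥ 80% valid required, both variances > 0), small enough to stay local |
| histogram `bin_width` | 1e-4 (reporting), 1e-3 (synthetic experiments) | CDI units | 1e-4 resolves modes reported to four decimals; desk-scale scenes have few independent windows, so their mode estimate needs bins of ~5–10% of the distribution scale to be stable |
| buffer half-width | 15 000 | m | operational reach of the small drones that make field work impossible near a frontline; total width 30 km |

## Numerical choices

**Threshold semantics.** The two hysteresis levels are interpreted as
quantiles of the *nonzero* suppressed gradient magnitudes (with a relative
floor of 1e-8 × max so that convolution residue in flat regions cannot
dilute the distribution). An alternative reading — fractions of the single
maximum magnitude — was implemented first and rejected: with it, "strong"
seeds reduce to the handful of junction pixels near the global maximum,
entire weak contour networks drop out regionally, density maps acquire
large zero holes, and retention responds discontinuously when the maximum
shifts between dates. Quantile levels keep the retained fraction stable
across scenes and dates, produce dense maps with unimodal value
histograms, and preserve the chain's homogeneity: scaling the input by
c > 0 scales every retained amplitude by c with an identical retained set.

**Window arithmetic.** Metric window edges are converted to the nearest
odd pixel count (ties round up: 2 km at 10 m → 201 px); a centered window
needs odd extents; below 3 px the window is rejected. Borders are handled
by reflection. Windows containing invalid pixels average over the valid
subset; pixels with under 50% valid coverage are flagged invalid rather
than propagating invalidity aggressively, so cloud holes do not erode
whole regions at 201 px windows.

**Mode estimation.** Histogram bins are `[j·w, (j+1)·w)`; the mode is the
center of the maximal bin, ties broken toward the lower bin
(deterministic). Zones with no valid pixels are recorded as missing.

**Normalization order.** The later map of a pair is rescaled by
`k = mean₁/mean₂` over the stable mask before any differencing or mode
comparison. Degenerate cases raise: an empty stable mask (advice: lower
the threshold or enlarge the block), a zero later-date mean, k ≤ 0.

**Proximity experiment sign convention.** Each random point carries its
distance to the frontline and the CDI *loss* relative to the reference
year (reference minus current). Degradation concentrated at the line then
yields a negative Pearson correlation — loss shrinks with distance. With
the signed change `ΔCDI = CDI_t2 − CDI_t1` the same relationship appears
with positive sign; `proximity_correlation` reports the plain signed
convention, `proximity_experiment` the loss convention. The "median point"
is the coordinate-wise median of the (distance, value) scatter.

## The synthetic generator

`synth.generate_mosaic` emulates a steppe agricultural region in a red
band: a Voronoi mosaic of fields whose mean reflectance is drawn from a
bimodal mixture (dark closed vegetation ≈ 0.09, bright bare/senescent soil
≈ 0.41, jitter σ = 0.048) — red-band field reflectance is strongly
bimodal, and this gives the high-contrast boundaries on which quantile
thresholds operate; a quasi-regular grid of full-span linear features
(shelterbelts, field roads; 1 per km², mostly dark) that keeps the edge
network connected across the scene; and compact settlements (0.15 per km²)
anchoring high-contrast edges every few kilometers. Defaults: 512 px at
10 m (5.12 km), 150 fields, additive noise σ = 0.01, values clipped to
[0, 1].

Two inter-date operators act on a scene:

- `degrade_scene(r, d)` blends the scene with a heavily blurred copy
  (σ = 8 px): `out = (1−d)·r + d·blur(r)`, with `d` scalar or per-pixel.
  Each linear feature additionally disappears wherever the local `d`
  exceeds its per-feature resilience draw, so erasure is spatially local,
  nested in `d` (a trajectory of increasing degradation only loses
  features), and erases an expected fraction `d` for scalar `d`. This
  attacks exactly what the indicator measures — boundary contrast and
  feature presence — while barely moving mean reflectance.
- `perturb_radiometry(r, gain, noise_sd)` applies a global multiplicative
  gain and fresh noise, the disturbance the correction factor k must undo.
  The default reflectance range leaves headroom so gains in [0.5, 2] do
  not saturate, keeping the chain's homogeneity intact for gain-recovery
  experiments; those experiments deliberately skip the percentile stretch,
  which is itself a radiometric normalizer and would cancel the gain being
  recovered.

### What the generator does not emulate

Phenology and seasonal spectral change; within-field texture (crop rows,
moisture patterns); clouds; georeferencing error between dates; the
long-range heterogeneity of a real 100 km scene (water bodies, cities).
Passing tests therefore demonstrate that the chain responds correctly to
structural degradation, radiometric drift, and spatial degradation
patterns — not that real-scene CDI values or their absolute levels are
reproduced (synthetic modes sit near 0.1; the real regional case study's
modes sit near 0.015, reflecting far sparser contour cover at 10 m over a
full agricultural oblast).

## Problem sizes

Experiments run at sizes chosen to keep the full suite fast while
respecting the scale separations the statistics need: degradation
monotonicity on 512 px scenes with the 2 km window (scene-level mode over
five degradation levels, five seeds); gain recovery on one 512 px scene
pair per gain; the proximity experiment on 100 replicates of 256 px scenes
with a 1 km window and 1000 points; zone attribution (degrade only the
buffer, check only the buffer's mode moves) on a single 1536 px (15.4 km)
scene — per-zone modes need the zone an order of magnitude larger than the
window and the window well above the field-texture scale, which smaller
scenes cannot provide.

## Known limitations

- The mode of a windowed-density field is a coarse, high-variance summary
  on small scenes; zone-level conclusions need zones ≫ window ≫ texture.
- Quantile thresholds couple dates through the scene-wide gradient
  distribution: degrading a large fraction of a small scene shifts what
  counts as an edge elsewhere. Sensor noise anchors the distribution in
  realistic inputs, and the k-correction absorbs the level shift, but a
  set-level residual remains on desk-scale scenes.
- CRS handling is deliberately minimal (EPSG code + projected/geographic
  discrimination); reprojection and resampling are out of scope, inputs
  must share one metric grid.
- Thinning is a single morphological pass; sub-pixel edge localization is
  not attempted.
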