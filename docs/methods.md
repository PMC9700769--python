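# Methods

## The measurement

The package quantifies the connectivity of an endothelial cord network in
a 2-D grayscale frame by the distribution of areas enclosed by fully
connected network cycles ("loops of connectivity").  A loop is a bounded
background region completely surrounded by network foreground; its
contour area is reported in px² (arbitrary units) unless a pixel size is
configured.  Connectivity loss has two signatures — fewer complete
enclosures, and thickening of connections that eats into the enclosed
space — and both reduce the measure, which is what makes it a useful
degradation readout across culture passages or conditions.

Per frame the chain is: equalize → crop → blur → binarize → skeletonize →
graph/regions → record.  The stages and their assumptions:

### Preprocessing

* **CLAHE** (tile 64 px, clip factor 2.0).  Classic tiled formulation:
  per-tile 256-bin histograms clipped at `clip × mean bin height`, excess
  redistributed uniformly, transfer functions blended bilinearly between
  tile centres.  With one tile and no clipping this reduces exactly to
  global histogram equalization with the standard transfer function
  `round((cdf(v) − cdf_min)/(N − cdf_min)·255)`, which is what the unit
  oracles check (two-level images map to the intensity extremes; repeated
  application is the identity up to ±1 quantization).  The clip factor is
  expressed as a multiple of the mean bin height (the common convention in
  image-processing practice) rather than a [0, 1] fraction.  Defaults are
  standard microscopy practice; both are configurable.
* **Cropping the growth region.**  Auto mode takes the tight bounding box
  of the largest 8-connected bright component under a coarse Otsu
  threshold, padded by 3σ of the blur and clamped to the frame; a manual
  half-open ROI overrides it.  The crop offset is recorded so region
  coordinates can be mapped back to frame coordinates.  A frame with no
  bright foreground raises a "no growth region" condition which the
  pipeline converts to an all-zero record with a warning.
* **Blur**: separable Gaussian, reflective boundary, σ = 2 px by default —
  enough to suppress sensor noise without bridging distinct cords at the
  default cord spacing; σ = 0 is the identity.
* **Binarization**: Otsu's threshold (maximum between-class variance,
  foreground strictly above), then removal of foreground components
  smaller than 16 px² whose skeletons would otherwise inject spurious
  graph components.  Otsu was chosen because it is parameter-free and
  reproducible; a fixed threshold is available.  Thresholding runs after
  blurring, matching the stated stage order of the chain.

### Skeletonization

"Erode repeatedly but stop just before disconnection" is formalized as
sequential simple-point thinning: a border pixel is deleted only if its
3×3 neighbourhood shows exactly one 8-connected foreground component and
exactly one 4-connected background component touching the centre
4-adjacently — i.e. deletion changes neither components nor holes.
Endpoints (one neighbour) are kept so arcs do not retract.  Deletion is
sequential in raster order with north/west and south/east sub-passes per
iteration (limits directional drift); every deletion is re-validated
against the current raster, so the Euler summary (8-connected components,
4-connected non-border background components) is conserved *by
construction*, not statistically.  The 256-entry simplicity table is
built once by brute-force component analysis of all 3×3 configurations.

Two post-passes follow, iterated with thinning to a fixpoint:

* **2×2 block repair.**  Four arcs meeting diagonally can leave a 2×2
  core in which no pixel is individually deletable (removing any one
  strands an arc).  If the original mask still has a spare pixel adjacent
  to the core, the junction is re-routed through it (the addition is
  accepted only if the Euler summary is unchanged and re-thinning removes
  the block), keeping the skeleton inside the mask.  If the mask itself
  is exactly such an irreducible crossing the block remains — a known,
  deliberately undisturbed limitation; none survives in any suite the
  tests exercise.
* **Spur pruning** (default 5 px): endpoint branches shorter than the
  limit and terminating at a junction are deleted from the free end
  inward, which provably cannot change components or holes.  Whole
  components (arcs with two endpoints) are never pruned.  Pruning can
  expose newly deletable corner pixels, hence the thin↔prune fixpoint
  loop; this also makes skeletonization idempotent.

Foreground uses 8-connectivity and background 4-connectivity throughout.
This standard planar duality prevents diagonal leaks that would merge
adjacent loops, and makes the loop count of a connected border-free
skeleton equal the cyclomatic number E − V + 1 of its graph.

### Graph and regions

Pixels with ≠ 2 skeleton neighbours, merged over 8-adjacency into
clusters, become graph nodes; maximal 2-neighbour chains become edges
with their pixel path and Euclidean length; a pure cycle gets one anchor
node and a self-loop.  Cluster merging is what keeps phantom
micro-triangles inside thick junctions from inflating the cycle count.

Loops are 4-connected background components not touching the frame
border ("contour detection" as border-excluded labelling — the region set
is identical to what a contour tracer finds, with simpler exactness
arguments; the traced sub-pixel contour of each region is still exported).
Each loop reports

* `area_px` — raw enclosed pixel count (used by the exact conservation
  identity: enclosed + border-connected background + skeleton = frame
  area);
* `area` — the headline estimate `(area_px + boundary_px/2 − 1) ×
  pixel_area` (Pick's formula, `boundary_px` = bounding skeleton pixels).
  Loops are delimited by cord centerlines, and the raw count misses the
  half-pixel strip between the last background pixel and the centerline —
  a bias of about half the loop perimeter (≈ 6% for a radius-15 circle).
  The correction makes measured areas agree with analytic centerline
  polygon areas to ≲ 3–4% across the validation suite.

The per-frame record carries loop count, mean/median/total enclosed
area, skeleton length, junction/endpoint/component counts and the
cyclomatic number.

### Series comparison and the headline statistic

`compare_series` takes replicate runs per condition, reports per-time
mean ± SEM, the difference curve, and a seeded percentile bootstrap
(default 2000 resamples) CI of the terminal-frame difference; replicate
values are sorted before resampling so replicate order is irrelevant.

The headline series is **total enclosed area**, not the mean loop area.
Under nested cord loss the total is provably non-increasing: deleting an
interior wall merges two loops whose combined area is conserved, while
deleting a peripheral wall opens a loop and removes its area.  The mean,
by contrast, transiently *rises* whenever merges dominate (fewer, larger
loops), so it does not track degradation monotonically; it is still
reported per frame for users who want the distribution's location.

## The synthetic generator

Real time-lapse data for this assay is not publicly available, so
validation uses generated images whose topology is exact.

* **Geometry.**  Cords are the ridges of a Voronoi tessellation of
  `n_seeds` uniform points with a minimum pairwise separation of 0.7× the
  mean nearest-neighbour spacing at that density.  The separation keeps
  every interior cell wide enough (inradius ≥ half the separation) that a
  default-width cord plus blur cannot fill a loop — matching real cord
  meshes, whose loops are much wider than the cords.  Only ridges lying
  entirely inside a margin box (frame inset by 8 px) are drawn; ridges
  crossing the box are dropped whole, so every free cord tip is a true
  Voronoi vertex shared with any nearby retained ridge, and the rasterized
  topology equals the vector topology (clipping at the box instead would
  put free tips at arbitrary mutual distances, and tips closer than the
  cord width would fuse into loops the ground truth considers open).
* **Ground truth.**  The retained segments form a planar graph; bounded
  faces are enumerated by polygonization of the segment arrangement, with
  analytic (shoelace) areas.  Per connected component the bounded-face
  count equals E − V + 1; the tests assert this against an independent
  Euler-formula oracle on every generated truth.
* **Degradation.**  Each edge carries one uniform mark; dropout level *d*
  removes edges with marks below *d*.  Marks are drawn from a stream
  independent of the level, so removal sets are nested across a series
  and ground-truth face count and total face area are monotone
  non-increasing — the axis standing in for passage-dependent loss of
  complexity.
* **Corruption.**  Rendering draws integer-raster centerlines thickened
  to `cord_width` by an exact distance threshold (foreground 200,
  background 40 in 8-bit), then applies a multiplicative linear shading
  ramp of seeded random direction (peak drop `illumination_amplitude`,
  default 12) and additive Gaussian noise (`noise_sd`, default 6 ≈ 2.4%
  of the 8-bit range — typical of well-exposed widefield frames), clipped
  to [0, 255].  Ground truth always describes the retained, pre-noise
  geometry.
* **Time lapse.**  Frame *k* of *n* draws the first ⌈k/n·|E|⌉ edges with
  the same corruption fields, so cords appear progressively and the last
  frame is pixel-identical to the single-frame render.

What the generator does **not** emulate: curved or tapering cords,
cell-body blobs at junctions, texture inside cords, focus drift, frame
registration error, or gradual cord thinning before rupture.  Passing
tests therefore demonstrate correctness of the measurement chain on
networks with known topology under noise and shading — not segmentation
robustness on every real-world artifact.

## Numerical and validation choices

* All randomness flows through `numpy` generators seeded from explicit
  integers (independent child streams for layout, dropout, noise,
  shading), so identical configurations are bit-reproducible, and two
  identical `run` invocations produce byte-identical CSVs (fixed float
  format, no timestamps in data files).
* Validation problem sizes: 384×384 frames; 20 networks spanning 9–60
  seeds for recovery checks (exact loop counts, face areas within 10%,
  measured worst ≈ 3–4%); 100 random closed Bernoulli masks (100×100) for
  topology preservation; 20 seeded series × dropout {0, 0.2, 0.4, 0.6}
  for the monotone-degradation sign test (α = 0.01) and the intact vs
  degraded bootstrap separation.  The noisy condition uses noise at 5% of
  the dynamic range plus a 10% shading ramp.
* Degenerate inputs are defined events, not crashes: empty mask → empty
  skeleton; constant frame under Otsu → "degenerate histogram"; no bright
  region in auto-crop → "no growth region"; the pipeline converts these
  to zero records with warnings.

## Known limitations

* Cord width is not normalized out: thicker cords shrink enclosed areas
  by construction.  This matches how the measure responds to "thickening
  of connections" but means the metric conflates width and topology; use
  the per-frame junction/length fields to disambiguate if needed.
* Areas are measured on the skeletonized network, not the pre-thinning
  mask (a flag on `enclosed_regions` input selection is unnecessary since
  any `Skeleton`-shaped raster is accepted — pass a mask-derived object
  for sensitivity analysis).
* The mean loop area is non-monotone under degradation (see above); use
  the total, or the full distribution, for trend claims.
* Physical calibration is optional; without it areas are arbitrary units,
  consistent across frames of a run but not across magnifications.
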