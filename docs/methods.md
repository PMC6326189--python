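# Methods

`vertseg` implements a semi-automatic segmentation pipeline for vertebral
bodies in 2-D sagittal lumbar-spine MR images. The user supplies exactly one
rectangular ROI (center, width `lx`, height `ly`) around any single
vertebral body; everything else — locating the remaining bodies, adjusting
each ROI, delineating each body — is automatic. This note records the model
assumptions, the parameters that matter, and the design choices made where
the procedure was genuinely open.

## Imaging model and assumptions

The pipeline assumes:

* a roughly vertical stack of vertebral bodies (supine sagittal
  acquisition), each shaped like a rounded rectangle;
* a dark cortical rim delineating each body against brighter trabecular
  interior, with intervertebral discs between bodies (T2-like contrast:
  disc > body > background > rim);
* approximately repeating appearance from one body to the next, so that
  normalised cross-correlation against the user's template finds the
  others;
* limited rotation per body (|angle| ≲ 30°, e.g. kyphosis/lordosis or a
  tilted acquisition).

All decision rules are contrast-relative (correlation is illumination
invariant, Canny thresholds are gradient quantiles, the line rules work on
intensity-cluster ranks), so rescaling the image by any positive constant
changes nothing. Images are normalised to [0, 1] on load.

## Stage 1 — body detection by correlation

The user template is matched everywhere by zero-mean normalised
cross-correlation (ZNCC). The map is computed exactly — per-window mean
removal and BLAS block products rather than FFT — because downstream logic
compares peak scores across the whole image and the map doubles as a
verification target against a brute-force oracle; border windows and
(near-)constant windows are suppressed.

The global peak `p1` recovers the user's body. Its `lx/3 × ly/3`
neighbourhood is suppressed ("1/3 of the ROI size" read as side lengths),
and the next accepted peak `p2` defines the reference distance
`d = |p2 − p1|`. Two openings had to be closed here:

* **`p2` selection.** Near-identical bodies score within noise of one
  another, so the raw second argmax can land two pitches away, after which
  the search skips every other body. `p2` is therefore the *nearest* local
  maximum to `p1` that passes the same acceptance threshold used everywhere
  else (`β`· best remaining score, `β = 0.6`) and lies at least
  `max(lx, ly)/2` away. If no such peak exists the image is declared to
  contain a single vertebra; a too-close second peak raises a degenerate
  reference distance error.
* **Step direction.** Subsequent searches step by the *vector* `p2 − p1`
  (magnitude `d` along the detected stacking axis), not by a purely
  vertical offset. For upright spines these coincide; for whole-image
  rotations up to 30–45° the vector step keeps the `lx × ly` search window
  on the next body. Search proceeds in both directions along the axis,
  accepting a window peak only if its score reaches `β`·score(`p2`),
  suppressing each accepted neighbourhood, stopping at the image border or
  below threshold, with a hard cap of `max_bodies` (default 8).

### Disc-based horizontal correction

A disc template of width `lx` and height `ly/2` is cut immediately above
the user ROI and matched by the same procedure. Disc positions localise
more sharply than body positions, so bodies whose position disagrees with
the adjacent discs get corrected. Two generalisations over the naive
"compare columns" rule, both of which reduce to it for an upright spine:

* positions are compared in the coordinate *perpendicular to the spine
  axis*, so the correction stays meaningful in tilted images;
* because the disc template is cut relative to the user ROI, every disc
  peak shares one systematic offset from the spine line (zero when
  upright); deviations are therefore measured relative to the *median*
  body-to-disc offset, and a body is corrected only when its deviation
  exceeds 10% of `ly`. Disc results are discarded wholesale if the disc
  spacing disagrees with `d` by more than 35% (the template latched onto
  something else).

## Stage 2 — per-ROI refinement

**Orientation.** Canny edges (`σ = 1.4`, hysteresis at the 70th/90th
gradient-magnitude quantiles) are Hough-transformed; the number of occupied
ρ-bins at angle θ measures the extent of the edge set projected at that
angle, which for a rectangle-like outline is minimal along the object's own
axes. Because the minimum can fall on either axis, the argmin is taken over
the full half-circle and reduced mod 90° to (−45°, 45°]; tied minima are
reduced first and then resolved by their median. The estimate is computed
on a 1.4×-enlarged analysis window cut down to its *largest connected edge
component* — the body rim is the longest edge curve in the neighbourhood,
while discs and neighbouring bodies contribute separate components that
otherwise bias the extent measure. The ROI is then counter-rotated (up to
two passes; a second pass removes most residual).

**Extent.** Edge counts are projected per column (`Px`) and per row
(`Py`). A side is "present" when the maximum of its half-profile reaches
`α` times the central value *and* at least half of the half-profile's
overall maximum, with three border pixels excluded. The second condition
and the border exclusion handle a rim sitting exactly on the crop border
(its blur tail leaks inward); `α` defaults to 3.0 because the central
value on a clean raster is just the 2-px crossing count of the lateral
rims and staircase rasterisation alone produces 2× fluctuations — a true
endplate projects body-width counts, an order of magnitude higher. Failing
sides grow outward by `ceil(0.1 · side)` per iteration, at most 50% per
side, clamped (with a warning) at the image border. The operation is
idempotent once converged.

## Stage 3 — segmentation

Vertices are estimated from the refined ROI's edge projections:
`bL/bR` are the argmax of `Px` over the left/right half-intervals, `bU/bD`
likewise for `Py` (ties resolve toward the ROI border). Vertex location
uses the *unpadded* refined crop — refinement guarantees it tightly
contains the body, whereas a padded crop pulls disc edges into the
projections — while all subsequent work happens on a crop padded by the
band spacing so boundary bands never exit the ROI.

The boundary neighbourhood is partitioned into four rectangular bands of
half-width `s = max(3, ceil(0.08 · min(lx, ly)))` straddling the vertex
rectangle's sides, plus eight corner triangles (each 2s × 2s corner square
split along its outer-to-inner diagonal; the triangle adjoining U/D is
processed like those bands, the one adjoining L/R like the lateral bands).

* **Superior/inferior (U/D) bands** — minimum-cost monotone path across the
  band: one node per column, steps to the three adjacent rows, step cost =
  intensity of the pixel entered. Dynamic programming finds the optimum,
  which is identical to the s/t min-cut of the same chain graph; ties
  prefer staying level, then moving up. Raw intensities are used (the
  clustering below is introduced only for the lateral rules). The dark
  cortical rim is the cheapest traversal, so the path tracks the mid-rim
  line.
* **Lateral (L/R) bands** — the working crop is k-means-clustered into 10
  intensity levels (clustering runs on the unique intensity values,
  weighted by count, 10 restarts, fixed seed; ranks 1–10 ascend with
  cluster center). Each horizontal line of the band is classified by its
  valley/peak structure relative to the base `B` (the interior end of the
  line, or the nearest peak to it) and the reference `R = ceil(Y(B)/2)`:
  Case 1 — a valley below `R` with a farther peak at least 2 cluster
  stages above it, the peak itself reaching `R`: the boundary is the
  minimum between that peak and the base (ties toward the base). Case 3 —
  no valley at all. Case 2 — everything else (including the shallow-valley
  profiles the written rules leave unassigned — folding them into Case 2
  keeps the classification total and mutually exclusive). Cases 2 and 3
  take the point nearest the base whose value equals `ceil(Y(B)/3)`,
  falling back (logged) to the band end when no point attains it.
* **Corner triangles** are padded to parallelograms by replicating each
  line's terminal pixel (empty lines copy their nearest non-empty
  neighbour), processed with the matching band method, and boundary points
  found in padded cells are projected back onto the hypotenuse.

A cubic polynomial is fitted per side; points deviating more than
`δ = 3 px` are replaced by the curve value. The four sides join into a
closed contour, which is mapped back to image coordinates through the ROI
transform and rasterised (polygon interior plus the contour pixels
themselves — the path runs through mid-rim tissue). The largest 4-connected
component is kept.

## Evaluation

Dice similarity `2|A∩B|/(|A|+|B|)` (two empty masks ≡ 1.0, a documented
convention), voxel counts, physical volume (count · spacing² · thickness,
defaults 0.39 mm and 3 mm), and mean Euclidean center error with bodies
matched by vertical rank (the stacking invariant makes assignment
unambiguous; unmatched bodies are counted as detection failures, not
distances).

## Synthetic phantom

The generator renders what the method assumes and nothing more: rounded
rectangles (superellipse, exponent 4) of 64 × 44 px (≈ 25 × 17 mm at
0.39 mm/px) with a 2 px darkest rim, vertical pitch 64 px, discs as bright
ellipses between bodies (tilted with the mean of the adjacent endplates),
per-body size jitter ±3%, optional per-body rotation, additive Gaussian
noise (fraction of dynamic range) and a smooth multiplicative quadratic
bias field. Ground truth (masks, centers, disc centers, rim outlines) is
analytic and pre-noise. `rotate_dataset` rotates image and truth together
about the canvas center, expanding the canvas so nothing clips.

**Truth convention and its consequence.** The truth mask is the body
*including* the full cortical rim, since the rim is part of the vertebra.
The segmented boundary tracks the mid-rim line (the darkest path), so even
a perfect run concedes roughly a 1–2 px ring: erosion analysis puts the
attainable DSC ceiling near 0.95–0.96 at the default geometry, and clean
phantoms measure 0.93–0.95. This mirrors how the method behaves against
manual references on real data, where raters outline the outer cortical
margin. What the phantom does *not* emulate: trabecular texture, partial
volume at real acquisition resolution, pathology (fractures, severe
degeneration), posterior elements overlapping the bodies, or through-plane
effects — so passing phantom tests demonstrates the geometry-driven logic,
not clinical performance.

## Problem sizes and numerical choices

Phantom images are ~300–500 × 160 px with 3–6 bodies; test and acceptance
runs use 10–20 seeded phantoms per property, enough for stable means at the
stated bounds. Argmax ties break to the smallest row then column;
rasterisation rounds half away from zero; rotation angles live in
(−90°, 90°] with positive = counter-clockwise in display space. Every
stochastic component (k-means restarts, phantom noise) is seeded; two runs
with identical inputs and config are byte-identical.

## Known limitations

* The up/down search termination (`β`, `max_bodies`) is a heuristic the
  original procedure leaves open; highly dissimilar adjacent bodies
  (e.g. opposite 20° rotations, 40° apart) can fall below the acceptance
  threshold and truncate the stack.
* The disc correction assumes a straight spine locally; strong scoliosis
  in-plane would violate the shared-offset model.
* Lateral boundaries depend on the 10-level clustering; on low-contrast
  images the valley/peak structure degenerates to Case 2/3 fallbacks,
  which is also where the original method reports its weakest boundaries.
* Single mid-sagittal slices only; no 3-D extension.
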