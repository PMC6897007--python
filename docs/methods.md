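# Methods

This note records the models behind `ctcpolyp`, the parameters that
matter, the design choices made where the design was genuinely open, and
what the phantom-based validation does and does not demonstrate.

## The synthetic phantom

No public CTC dataset ships with the package, so every quantitative claim
is exercised on a synthetic phantom with exact voxel-level ground truth.
The phantom emulates the imaging situations the pipeline must handle, not
abdominal anatomy at large:

- **Colon**: an air-filled tube (default radius 12 mm) following a gently
  curved S-path through the volume, wrapped in a 5 mm soft-tissue wall,
  embedded in a fat background that fills the whole field of view.  Default
  grid 40 × 128 × 128 voxels at (0.7, 0.7, 1.25) mm — in-plane pixel size
  inside the 0.546875–0.9765625 mm range typical of abdominal CTC, with a
  thin-slice protocol.
- **Haustral folds**: thin fin-like ridges (default 3 mm thick in the arc
  direction, 7 mm tall, running 8 mm along the colon).  In an axial slice
  a fold appears as a radial fin whose medial axis points into the lumen —
  the geometry the skeleton-based measurement is built for.
- **Polyps**: ellipsoidal caps on the wall with exact height/width ground
  truth; defaults are three polyps of 2.5–6 mm width, one sessile-ish and
  two flat.
- **Tagged fluid**: fills the gravitationally lowest fraction of the lumen
  (default 30%; gravity is the +row direction, supine convention; the
  surface is a horizontal plane).  Pool HU defaults to 500 ± 15: clinical
  orally tagged fluid measures several hundred HU, and the material table's
  +130 HU is the classification *threshold* for tagging contrast, not the
  pool mean.  At a 130 HU pool the submerged wall would have a display-image
  contrast of ~21 grey levels — too faint for any edge detector — which is
  not a regime real tagging produces.
- **Air–contrast transition layer**: a 1–2 voxel band of partial-volume HU
  (linear air/fluid mix) synthesized on the air side of every air/fluid
  face; its removal is an explicit cleansing step.
- **Pseudo-enhancement halo**: an exponential HU elevation
  `A·exp(−d/λ)` (defaults A = 60 HU, λ = 1.5 mm) added to wall and fold
  tissue near tagged fluid, emulating the artifactual brightening of
  tissue adjacent to high-density contrast.
- **Noise and texture**: per-material HU jitter with sd = tolerance/4 plus
  global Gaussian noise (default sd 1 HU).  The defaults are chosen so that
  ≥99% of each material's voxels stay inside its nominal ± band, which is
  what the interval classifier assumes; real scanners are noisier, and both
  knobs are exposed.  All random fields are full-volume and keyed to the
  seed, so truth masks are noise-independent and raising the fluid level
  (`submerge_polyp`) leaves every tissue voxel bit-identical.  The halo
  skips polyp truth voxels so that polyp HU — and hence size ground truth —
  is invariant under submersion.
- A 12 mm air pocket ("small bowel decoy") in the background exercises the
  distension-diameter blob filter.

What the phantom does **not** model: extra-colonic organs, beam hardening
and scatter, motion, collapsed segments, stool of heterogeneous density
(only a simple partial-tagging flag), and anisotropic texture.  Passing
phantom tests therefore demonstrates the internal consistency and
geometric correctness of the pipeline, not clinical-grade performance.

## Colon segmentation

Per axial slice: adaptive smoothing → windowing → Canny → connected
components → distension filtering → scan-line stitching; slices are
stacked without enforcing 3-D coherence (the paper-style 2-D design).

- **Adaptive smoothing** is a Lee-type local-variance-weighted average
  (5×5): flat regions collapse to the local mean (noise sd reduced well
  over half), high-variance neighbourhoods — edges — keep their values
  (gradient reduced <10%, edge shift ≤1 px).
- **Windowing**: edge detection runs on the 8-bit display image at
  C = −200 / W = 1500 HU, the window that renders the air lumen black
  against soft tissue; the hysteresis thresholds (low 40, high 100;
  useful band up to 50:120, ratio restricted to 2:1–3:1) are in display
  gradient units.
- **Canny**: 5×5 Gaussian (σ 1.4), Sobel gradients, non-maximum
  suppression with the direction quantized to {0°, 45°, 90°, 135°} (ties
  toward the lower angle), hysteresis by connected components.  A
  morphological closing bridges 1-pixel gaps (notably the double edge
  across the air–contrast transition layer) before blob labeling; each
  retained blob set is re-thinned, so the final contour is exactly one
  pixel thick (its erosion is empty).
- **Distension filtering**: blobs with maximal axial diameter under 20 mm
  (inclusive boundary at 20 mm) are not colon and are discarded; the
  diameter is the max pairwise distance of boundary points in mm (convex
  hull accelerated).
- **Scan-line stitching**: for each scan line the pixels between the
  extreme boundary points are stitched; the region is the union over four
  line families (rows, columns, both diagonals).  A protruding structure
  shadows the lines parallel to its protrusion, but some family is always
  within 22.5° of perpendicular and crosses both of its flanks, so folds
  and polyps are retained.  For the diagonal families each boundary pixel
  is registered on the neighbouring line ids as well, because a 45° line
  can otherwise pass between two diagonally adjacent contour pixels.
  Interior pixels carry the original HU.

**Known limitation — base skin of wall-flush caps.**  A polyp sitting
directly on the wall indents the interface; the thin skin of the cap
between its own dome contour and the wall carries no edge on the wall
side and lies outside the convex hull of the interface, so no
between-extremes fill along any direction can reach it.  Empirically the
missing voxels are confined to within ~2 in-plane pixels of the wall and
the cap bodies remain 66–92% inside the VOI; fin-like folds — whose bases
the method is designed to locate — are retained at ≥98%.  This is why the
VOI overlap plateaus near 96% rather than 100%, and why pipeline-level
size measurements are quoted to ±1 voxel.  Re-stitching a stitched
region's own boundary is exactly idempotent on convex regions and grows a
region with structure indentations by under 5% (a one-off
convexification).

The truth "colon region" used for overlap scoring is the lumen disc plus
the mucosal surface pixels whose centres lie within half an in-plane
pitch of the geometric interface — the 1-pixel contour the detector aims
for straddles the interface by exactly that much.

Fold and polyp default positions avoid the exact scan-axis extremes
(0°/90°/180°/270°): a structure centred on an extreme has its base beyond
the contour's outermost scan line, the worst case of the limitation
above.

## Electronic cleansing

The lookup table anchors air at −1000 HU for every kVp (air defines the
HU scale) and recomputes the other interval centres from a built-in
attenuation-ratio table with anchors at 100 and 120 kVp (linear
inter/extrapolation across the supported 80–140 kVp; tolerances constant;
intervals verified pairwise disjoint).  At 120 kVp the table is exactly
the observed colonic-content values; at 100 kVp iodinated contrast rises
to ~165 HU, fat drops to ~−96, soft tissue ~+57.

The cleansing sequence and its guards:

1. **remove_tagged** — contrast-labeled voxels → replacement HU
   (−1000, so downstream segmentation sees clean lumen).  Soft-tissue
   voxels are never candidates: submerged structures survive bit-exactly.
2. **remove_air_contrast_layer** — unclassified voxels within 2 voxels
   (6-connected) of both air and contrast are deleted, with two guards:
   not 6-adjacent to classified soft tissue, and HU below the soft-tissue
   interval (halo-elevated tissue sits above it and must not be eroded).
3. **correct_pseudo_enhancement** — voxels within 4 mm of contrast whose
   HU exceed the soft-tissue or fat interval by at most 80 HU are treated
   as halo-elevated tissue of their *nearest* tissue class (EDT
   assignment, so air/contrast partial-volume values near the wall are
   never mistaken for elevated fat); per class the halo amplitude is
   fitted by least squares to `A·exp(−d/1.5 mm)`, subtracted, and the
   result clamped into the interval.
4. **denoise_lumen** — a lumen voxel (air-labeled or replaced) is set to
   its 3³ median only when it deviates by >150 HU *and* the median itself
   is air-like (< −700 HU).  The second guard prevents wall-adjacent air
   voxels from being pulled to tissue values, which would cascade on
   repeated application; with it, the whole EC chain is exactly
   idempotent.

## Measurement

Measurement is 2-D on the axial slice with the largest cross-section of
the structure (the 3-D thinning variant was deliberately left out).
Skeletonization is topology-preserving thinning (scikit-image); the
medial axis is the skeleton minus boundary-coincident points, ordered by
a Dijkstra pass from the wall-nearest point to its geodesically farthest
point.

- **Height** = geodesic axis length, extended at the root by the distance
  to the wall contour and at the tip by the inscribed radius (thinning
  insets a skeleton by half the local width at each end; the extension is
  exact for a wall-attached rectangle), minus one pixel of double-counted
  end cap.
- **Width** = maximal chord along Gram–Schmidt normals: the tangent is a
  central difference over ±2 axis points (one-sided at the ends), the
  seed for orthogonalization the coordinate axis least aligned with it;
  chords are ray-marched at 0.25-voxel steps in physical (mm) space, so
  anisotropic spacing is handled and the convention reproduces digitized
  extents exactly on axis-aligned bars.  A single-point axis (tiny
  structures) falls back to the maximum chord over all directions.  Ties
  in the maximum are resolved to the axis point nearest the base.
- **Classification**: polyp iff height < 6 mm, else fold candidate;
  sessile iff height > 1.5 × width, else flat; size category by width
  (≤5 mm, <10 mm, ≥10 mm — a partition of all positive widths).  The
  sessile rule follows the reference convention verbatim even though it
  inverts the usual radiological sense of "sessile" (broad-based); the
  1.5 factor and comparison direction are module constants, and the
  reported "size" is the width (both height and width are in the JSON).

Accuracy, measured on truth masks across 30 random single-polyp phantoms
spanning 2–12 mm widths: mean absolute width error ≈ 0.5–0.7 mm (≤1
in-plane voxel), no significant bias (paired-t p ≫ 0.05).  At oblique
wall positions the effective lattice pitch is √2 × pixel, which is the
appropriate "one voxel" there.

## Evaluation

Volumetric overlap is the Jaccard index as a percentage (both-empty → 100
by convention).  Confusion statistics: TPR = TP/(TP+FN),
TNR = TN/(TN+FP), accuracy = (TP+TN)/total; the printed form truncates
(does not round) TPR/TNR at one decimal and accuracy at two, matching
radiological reporting of 14/17 as 82.3%; full-precision values are
always available.  The paired t-test uses dof = n−1 and the exact t
distribution; all-zero differences report p = 1 with a warning.
Per-polyp matching is greedy nearest-neighbour within a configurable
5 mm centre distance; truth-negative structures (folds) with no detection
within tolerance count as true negatives.

The reference study's two printed t values for the same 70-polyp
comparison (0.9937 in the abstract, 1.6771 in the discussion) cannot both
follow from the printed group summaries, and neither is recoverable
without the per-pair data; the package recomputes only the dispersion
statistics (SEMs, dof) that are derivable, and they match to four
decimals.

## Problem sizes

Default phantoms are 40 × 128 × 128 voxels (≈0.65 M); segmentation of one
phantom takes ≈0.5 s and full cleansing ≈2 s on one CPU, so the
acceptance run (10 phantoms for overlap, 30 single-polyp phantoms for
recovery) completes in well under a minute and the test suite in a few
minutes.  These sizes exercise every geometric regime of the method
(folds, submerged structures, partial-volume layers) at a quarter of the
clinical 512² matrix; nothing in the implementation depends on the matrix
size.
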