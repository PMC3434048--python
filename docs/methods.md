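# Methods

## Units and conventions

All spacings are stored in µm, volumes in mm³, masses in g, densities in
g/cm³; conversions are centralized in `mrvolumetry.core`. Image axes are
ordered (slice, row, column), with the spacing triple in the same order;
file readers (NIfTI via nibabel, TIFF via tifffile) reorder into this
convention on load, and NIfTI spacing is taken from the header zooms
(mm, converted to µm). Voxel centers sit at integer voxel coordinates.

A volume whose slice spacing exceeds twice the largest in-plane spacing
is treated as a thick-slice 2D stack (e.g. 700 µm slices over
150×200 µm pixels); everything else is treated as an isotropic-ish 3D
volume. The two share one representation — only connectivity defaults
and the `seg2D`/`seg3D` provenance tag differ.

## Segmentation pipeline

The pipeline is a batch reconstruction of an interactive workflow, so
that runs are scriptable and replayable: the reference region, exclusion
polygons and fill seeds arrive as JSON, and each produced mask carries a
provenance list of the operations applied.

* **Threshold.** The global threshold is the arithmetic mean intensity
  over the voxel centers covered by a planar reference polygon drawn
  across the tumour border. For a region with equal amounts of the two
  tissue classes this is exactly the class midpoint. Tumours are
  hyperintense, so the comparison is `intensity >= threshold`; the
  direction and the tie (≥ rather than >) are fixed conventions.
  Per-slice adjustment is an absolute replacement threshold for that
  slice, not a multiplier — the simplest semantics consistent with
  adjusting a failing slice independently.
* **Exclusion polygons.** Membership is a voxel-center-in-polygon test
  (shapely). Whether a voxel whose center lies exactly on the polygon
  line goes to tumour or background measurably shifts small-tumour
  volumes, so it is an explicit `boundary_policy` parameter; the default
  assigns boundary voxels to background (they are excluded).
* **Interior fill.** Automatic mode fills every background component
  not connected to the image border (scipy.ndimage hole filling) —
  the non-interactive equivalent of growing a seed in each enclosed
  low-signal region; seeded mode converts only the components
  containing a user seed (a seed placed in tumour warns and is
  ignored). Connectivity is 6-neighbourhood in 3D for isotropic
  volumes and 4-neighbourhood per slice for thick stacks — the
  conservative choice (no diagonal bridges) — and is overridable.
  Single-slice volumes are always filled in-plane: in a 3D fill a
  one-slice hole would be "open" towards the array's z-faces and never
  fill.
* **Mass.** Tumour voxel count × voxel volume × density (default
  1.0 g/cm³). Mass is linear in count and density by construction.

## PVE simulation

Geometry is normalized by the voxels-per-diameter ratio *d/a*: the
bounds depend on diameter and voxel edge only through it (plus the
origin alignment). The grid always extends one spare element beyond the
sphere; results are exact integer counts, and reported percentages keep
full precision internally, rounding to whole per cent only in tables.

Two geometric details matter at the one-percent level and are therefore
explicit parameters rather than baked in:

* **Origin.** "Coinciding origins" can put the sphere center on a grid
  vertex or at an element center. The default is `vertex`; both are
  selectable. For even integer ratios the vertex alignment makes the
  inside/intersected counts symmetric across octants.
* **Classifier.** `exact_box` is the exact box–sphere test: a box is
  inside iff its farthest corner is within the radius, outside iff its
  nearest point is beyond it, intersected otherwise (corner-counting is
  not exact: a sphere can pierce a face without containing a corner).
  All comparisons are made on squared distances so ties on integer
  grids resolve exactly. `rim_circle` (default) reconstructs a
  slice-wise procedure: each one-element-thick section is classified
  against the sphere's cross-section circles at the section's two
  z-boundaries — tumour iff fully inside the smaller circle (identical
  to the exact farthest-corner test, so the underestimate bound is
  classifier-independent), PVE iff the element's in-plane footprint is
  crossed by either boundary circle; in the polar cap sections the
  small circle degenerates to the pole point, whose containing elements
  still count as PVE. `rim_circle` misses elements that straddle the
  rim strictly between the two boundary circles, so its overestimate is
  slightly below the exact one (≈ 5 points at ratio 12, < 1 point by
  ratio 45); it is the variant that reproduces the historically
  reported bounds table (+6/−6, +10/−10, ~+15/−15, +39/−31 at ratios
  70/45/28/12) and is kept as the default for continuity with those
  numbers. Analyses that need the strict geometric envelope (e.g. the
  phantom-recovery checks below) use `exact_box`.

The sweep covers 3–9 mm diameters × 100–250 µm voxels by default.
|over| and |under| errors decrease monotonically with the ratio *within
each fixed voxel-edge series*; across the merged sweep, nearby ratios
coming from different diameter/voxel pairs can jitter by up to about one
point because the sphere–grid alignment differs, so monotonicity is
asserted per series, and the bracket Ṽ₋ ≤ V ≤ Ṽ₊ on every row.

## Phantom generator

The generator emulates what the segmentation needs from a T2-weighted
tumour image: a hyperintense ellipsoid (default intensities 100 vs 20,
chosen for clear bimodality — real tumour contrast-to-noise is not
otherwise constrained) with partial-volume edge voxels, optional
enclosed low-signal cores, optional Gaussian blur as a PSF stand-in,
and additive noise. Per-voxel tumour occupancy is computed by
supersampling (default 4³ samples per voxel, raised to 8³ when the
tumour spans fewer than 8 voxels across), so the rendered intensity sum
conserves the analytic volume V = (4π/3)·a·b·c to well under 1 %. The
analytic volume is the primary truth; the 0.5-occupancy mask is a
secondary, unbiased discretization of it. Noise is Gaussian by default
(sufficient for threshold testing); a Rician mode exists because
magnitude MR noise is Rician. Intensities are clipped at zero after
noise. Every spec carries a seed; identical specs render
bit-identically.

The phantom grid always has an even number of voxels per axis with the
ellipsoid at the field-of-view center, i.e. the sphere center lies on a
voxel vertex — which is exactly the `vertex` origin mode of the PVE
simulation, so `exact_box` bounds at the matching ratio bracket any
occupancy-threshold segmentation of a noise-free sphere phantom
deterministically.

What the phantoms do **not** emulate: anatomical background (organs,
skin, coil shading), texture inside the tumour, the RARE readout's
point-spread-function asymmetry, or motion. Passing phantom tests
therefore demonstrates the correctness of the geometry, thresholding and
unit bookkeeping — not robustness to anatomy-induced segmentation
failures, which is precisely what the manual exclusion polygons exist
for in practice.

The default cohort spans 0.01–2.28 g (the mass range the method targets)
including the 0.01/0.10/0.87 g sizes used in observer studies, rendered
at 160/200/240 µm isotropic and the 700×150×200 µm thick-slice
geometries.

## Agreement statistics

The coefficient of variation uses the sample (n−1) standard deviation —
for n = 10 repeats the population convention would read ~5 % lower, so
the choice is fixed and stated. Interobserver deviation is signed:
100·(observer − reference)/reference. Regression is ordinary least
squares of estimate on reference with r² the squared Pearson
correlation (scipy). When the predictor is the analytic phantom truth
there is no regression-attenuation toward zero, so the fitted slope of
segmented-vs-true mass should sit within the PVE band around 1.

Observer variability cannot be recomputed without the original raw
repeated measurements, so it is covered by construction-level checks
(CV of identical repeats is 0, scale invariance, signed-deviation
identities) plus a directional emulation: synthetic observers are
modelled as multiplicative jitter on the segmentation threshold
(`observer_threshold_study`), and on a small (< 0.2 g) noisy phantom
the thick-slice 2D geometry yields a larger mass CV than isotropic
160 µm voxels — more of its volume sits in partial-volume voxels, so
the same threshold shift moves more volume. No numeric target is
attached to this comparison.

## Problem sizes

Tests and the acceptance computation run the simulation at ratios up to
~102 (grids up to ~10⁶ elements, enumerated slab-wise) and phantoms up
to 2.28 g at 160 µm voxels (~108³ voxels at 4³ supersampling); both
complete in seconds on one core, which is why no smaller surrogate
sizes were needed.

## Known limitations

* The PVE simulation covers spheres only; real tumours are at best
  ellipsoidal, and the bounds for elongated shapes would be governed by
  the smallest axis rather than one diameter.
* `estimate_threshold` assumes the reference region is honest; a region
  that is mostly one class biases the threshold toward that class, and
  no automatic (e.g. histogram-based) threshold is provided by design —
  the reference-region mean *is* the method under test.
* Masks are uncompressed booleans in memory; volumes much beyond ~10⁸
  voxels would need a chunked implementation.
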