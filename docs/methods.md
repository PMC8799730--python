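# Methods

This note records the models, conventions and numerical choices behind
`edemaseg`, and what the synthetic experiments do and do not demonstrate.

## Region growing: acceptance rule and fixed-point semantics

The engine grows a 2D region per slice from a seed pixel S. A candidate
pixel P adjacent to the accepted set R is admitted iff

    |I(P) − I(S)| ≤ max( f · [max(R) − min(R)], τ0 )

with defaults f = 0.20, τ0 = 0, 8-connectivity. Growing is strictly
in-plane; a volume segmentation is the stack of independently grown
slices (multiple seeds per slice are grown independently and unioned).

Three aspects of this rule are underdetermined and had to be fixed:

* **Traversal order.** Since max(R)/min(R) evolve as R grows, naive
  queue-based growth depends on visit order. We define the result as the
  *least fixed point* of the acceptance operator: a pixel belongs to the
  region iff the rule admits it given the final accepted set reachable
  through admitted neighbors. The operator is monotone — accepting more
  pixels can only widen the range and hence the threshold — so the fixed
  point is unique and order-free. It is computed by synchronous frontier
  sweeps (every sweep admits all currently qualifying frontier pixels at
  once and updates the extrema), which re-examines pixels rejected under
  an earlier, smaller threshold. The test suite checks equivalence
  against an independent brute-force oracle (repeated full-grid scans to
  stagnation) on ~1200 randomized small slices.
* **Seed-only initialization is degenerate.** With R = {S} the range is
  zero and only exact-equality pixels could ever be admitted. The region
  is therefore initialized to the seed's `init_window` neighborhood
  (default 3×3, clipped to the frame), accepted unconditionally; τ0 is
  available as an absolute floor for seeds in perfectly uniform
  neighborhoods.
* **≤ vs <.** The comparison is implemented as ≤ (a candidate exactly at
  the threshold is admitted). On a uniform slice every pixel satisfies
  |I(P) − I(S)| = 0 ≤ 0, so the region floods the frame — a documented
  consequence, not an edge-case bug.

Two threshold modes exist. `dynamic` (default) recomputes the range as R
grows; `fixed` freezes the threshold at the initial neighborhood's
range. Only `fixed` mode is monotone in f (a larger fraction can only
add pixels); `dynamic` is exempt from that property because the
admission of one pixel changes the threshold seen by all later ones.

A structural consequence worth stating: in dynamic mode the final
threshold is bounded by ~25 % of the *initial window's* intensity range
(admitted values within ±t of the seed can widen the range only
geometrically, t′ ≤ 0.2·(range + 2t)). The rule therefore cannot flood a
region whose internal intensity spread exceeds a quarter of the seed
neighborhood's local range — which is precisely why range-fraction
growing under-segments textured or low-contrast edema and motivates
comparison against learned segmenters.

## Overlap indices and aggregation

For one mask pair, DICE = 2|R∩GTS|/(|R|+|GTS|), IoU = |R∩GTS|/|R∪GTS|,
VOE = 1 − IoU. The three are mutually consistent per pair
(DICE = 2·IoU/(1+IoU), machine precision). Conventions:

* **Empty–empty pairs score (1, 1, 0).** The ratios are 0/0 there;
  agreed absence is treated as perfect agreement. One-sided emptiness
  scores (0, 0, 1).
* **VOE is stored as a fraction** in [0, 1] and rendered as a percent at
  the reporting layer (both renderings are available); reported headline
  VOE values in the literature are not always on a consistent scale, so
  the fraction is the canonical internal unit.
* **Two aggregates are always reported**: pooled-voxel volumetric scores
  and the arithmetic mean of per-slice scores over slices where R ∪ GTS
  is nonempty. Published summaries rarely say which was used, and the
  two differ (the DICE/IoU identity holds per pair, not for means), so
  both are first-class.

## Phantom design

The phantom is a piecewise-simple validation object in the Shepp-Logan
tradition: an elliptical head (constant cross-section across the slab,
as in a head-scan field of view much smaller than the head), containing
one hyperintense ellipsoidal lesion. Default geometry follows a fused
T2-FLAIR study grid: 512×512 in-plane at 0.7211 mm, 0.625 mm slice
thickness, 109 slices, lesion semi-axes (15, 18, 14) mm so it spans
several tens of slices.

* **Intensities** (arbitrary units): background 10, brain tissue 100,
  edema 180. The 80-unit lesion/tissue contrast at tissue noise sd 5
  (16:1) idealizes the strong hyperintensity of vasogenic edema on
  T2-FLAIR.
* **Noise** is a per-tissue-scaled Gaussian random field, spatially
  smoothed in-plane (correlation length 2 px) to resemble tissue texture
  rather than sensor white noise. Default sds: background 2, tissue 5,
  edema 0 — the lesion interior is homogeneous by default. This is a
  deliberate idealization: per the threshold bound above, range-fraction
  growing cannot flood a region with appreciable internal texture, and
  the sharp high-contrast default is the regime in which the algorithm
  is well-posed. Tests that claim near-perfect phantom recovery
  therefore demonstrate correctness of the *engine*, not robustness of
  the *criterion* on realistic texture; nonzero `noise_sd["edema"]`
  exists precisely to study that failure mode.
* **Ground truth comes in two flavors**: `true_edema` (voxels inside the
  ellipsoid — the intensity support) and `gts`, the clinician-style
  delineation obtained by in-plane morphological dilation with a disc of
  radius `gts_margin_mm` (default 1.5 mm). Clinicians outline wider than
  the visible hyperintensity; the margin is a free parameter because no
  canonical value exists. With margin 0 the two masks coincide.
* **Diffuse boundaries** (`boundary_mode="diffuse"`) ramp the lesion
  intensity linearly down to tissue over `diffuse_rim_mm` beyond the
  ellipsoid, emulating lesions whose boundary strength is not obvious;
  the rim width in mm is measured along the mean semi-axis direction
  (exact geodesic thickness of an ellipsoidal shell is not needed at
  this fidelity). Rician noise and anatomical structure are out of
  scope.
* `rng_seed` fully determines the output bytes.

What passing phantom tests shows: geometric correctness (masks, spacing,
dilation), determinism, and that the engine recovers a sharp
high-contrast lesion essentially exactly (volumetric DICE ≥ 0.95, in
practice > 0.999). What it does not show: performance on real MR
texture, partial-volume boundaries, or multi-focal edema.

## Preprocessing conventions

* **Through-plane interpolation** resamples onto the uniform grid
  `first + k·thickness`, k = 0 … ⌊span/thickness⌋, each output slice a
  position-weighted linear blend of its two bracketing acquired slices
  (weights snapped at 1e−9 so coincident positions copy the original
  slice bit-exactly). The in-plane grid is untouched; the proprietary
  resampling of clinical fusion software is not reproduced. Note that a
  22-slice, 5 mm series spans 105 mm and yields 169 grid positions at
  0.625 mm; a smaller retained count in a clinical dataset reflects
  keeping only lesion-bearing slices, a selection this module leaves to
  the caller.
* **Augmentation** applies horizontal/vertical flips, rotation ≤ 15°,
  translation ≤ 10 px, zoom 0.9–1.1 and intensity scaling 0.9–1.1
  (geometric ops identically to image and mask; masks resampled
  nearest-neighbor so they stay binary; images bilinear; out-of-frame
  filled with 0; intensity ops image-only). Default accounting expands
  the inputs to an 800-pair pool = 700 model-building + 100 held-out,
  chosen by seeded sampling without replacement.
* **Splitting** uses round-half-up for the 80/20 train/validation sizes
  (700 → 560/140; a single item goes to train).
* All stochastic stages consume a `numpy` `default_rng` seed; in the
  pipeline every stage seed is derived from one global seed via
  `SeedSequence`, making whole runs byte-reproducible.

## I/O conventions

* Grids are (slice, row, col), 0-based; NIfTI files are written with the
  slice axis as the third stored dimension and spacing in the affine;
  PNG stacks are 16-bit gray with a JSON spacing sidecar (plain stacks
  without one fall back to the 0.7211/0.625 mm defaults with a warning);
  DICOM series are read-only, sorted by patient z position.
* Masks binarize as nonzero → 1 and are stored as {0,1} (NIfTI) or
  {0,255} (PNG).
* Polygon annotations rasterize by the even-odd rule with pixel-center
  containment: a pixel is inside iff a +x ray from its center crosses
  the boundary an odd number of times, with half-open edge handling so
  centers on a left/top edge are inside and on a right/bottom edge are
  outside (an axis-aligned rectangle with corners (1,1)–(3,3) covers the
  2×2 centers {1,2}²). Even-odd was chosen over nonzero-winding as the
  simplest well-defined rule for possibly self-intersecting hand-drawn
  contours.

## Problem sizes in the test suite

Oracle-equivalence checks run ~1000 randomized cases on slices ≤ 8×8
(growing) and mask pairs ≤ 16×16 (indices), where brute force is exact
and exhaustive enumeration of disagreement is feasible. Phantom-recovery
checks run once at the full default 109×512×512 grid; pipeline
reproducibility uses a reduced grid (14×64×64) since byte-identity is
scale-free. These sizes keep the suite in the seconds-to-a-minute range
while covering every code path at full default geometry at least once.

## Known limitations

* Growing is 2D per slice by design; no 3D connectivity.
* No automatic seed detection; `seeds_from_mask` (per-slice centroid of
  a reference mask, minimum area 9 px so the 3×3 window is meaningful)
  emulates an operator and is intended for phantom studies.
* No hole filling or small-component removal is applied by default.
* DICOM writing, RT-STRUCT contours, multi-label masks and CT–MR
  registration are out of scope.
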