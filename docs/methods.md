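# Methods

`agnorfract` quantifies argyrophilic nucleolar organizer regions (AgNORs)
— the near-black silver-stained dots that mark nucleoli in histological
sections — and asks whether their morphology separates pathology groups.
This note documents the models, estimators, defaults, and the design
choices that were genuinely open.

## The measurement chain

1. **Segmentation.** AgNOR dots are the darkest structures on a slide
   triple-stained with silver (dots), Nuclear Red (nuclei) and a green
   HRP chromogen (basal cells of benign glands). The rule set is fully
   explicit: a pixel is foreground when its mean RGB intensity is at or
   below `darkness_threshold` (default 80/255) *and* it is not
   green-dominant (green exceeding both red and blue by
   `green_margin = 25`); an optional binary opening and a minimum
   component size (`min_object_px = 12`, the silver-grain filter) clean
   the mask. Foreground connectivity is 8 (background 4); labels are
   assigned in row-major order of each component's first pixel.
2. **Morphometry.** Roundness follows the diameters-ratio convention:
   `sqrt(lambda1/lambda2)` of the pixel-coordinate covariance — the
   major/minor axis ratio of the moment-equivalent ellipse, 1 for a
   circle. A 1/12 per-pixel variance term keeps one-pixel-wide shapes
   finite. A `circularity` alternative (Crofton `perimeter^2 / 4*pi*area`)
   sits behind a switch; outputs record which convention was used.
   Areas are `pixel_area * pixel_size^2`; the per-image
   `total_normalized_area` is foreground pixels over total pixels,
   scaled by 1e6 (ppm of image area); `density` is dots per mm^2 of the
   calibrated frame.
3. **Fractal dimension.** Box counting: occupied-box counts across box
   sizes, least-squares slope of `log N` vs `log(1/s)`. Default sizes
   are powers of two from 2 px to `min(H, W) / 4`; per size the count is
   minimized over a 3 x 3 lattice of third-of-box grid offsets. Four
   half-box offsets were tried first and left an ~0.067 FD shift under a
   (7, 13)-px translation of the same mask; the 3 x 3 lattice brings
   that down to ~0.01, which is what a translation-invariant descriptor
   requires. Per-object FD is computed on the silhouette *outline* (the
   object minus its 1-px erosion) over roughly geometric sizes up to
   half the padded bounding box — small smooth dots then measure near 1,
   rugged ones higher. Objects under 8 px or with fewer than 3 usable
   scales return the flag value FD = 1 exactly, so the downstream value
   filter removes them explicitly rather than silently.
4. **Skeleton filter.** The whole-image dot mask is thinned
   (topology-preserving skeletonization) and spur branches are pruned by
   iterative endpoint removal (default 5 iterations); a component about
   to vanish keeps one pixel, so the component count of the source mask
   is preserved. The box-counting dimension of the pruned skeleton map
   describes the spatial repartition of the dots (ring-like vs
   space-filling) rather than their individual shapes.
5. **Value filter.** Before any averaging, objects with zero area,
   degenerate (or zero) roundness, or FD equal to 1 (within 1e-6) are
   discarded. Note that an exactly-1.0 *estimate* on a real dot is also
   removed — that is the filter's stated purpose (excluding dots whose
   boundary shows no measurable complexity, typically tiny smooth ones).
6. **Statistics.** Averaging is strictly hierarchical — image, then
   patient, then group, unweighted at each step; group means are means
   of patient means, never pixel or image pooling. Group comparisons use
   one-way ANOVA and Tukey HSD (Tukey–Kramer for unbalanced designs,
   `scipy.stats` underneath); the test suite cross-checks both against
   hand-written sums-of-squares and studentized-range computations to
   1e-8. Compartment agreement (epithelium vs whole tissue) uses Pearson
   correlation. The ANOVA unit defaults to the image (patient-level
   analysis is available through the aggregation helper).
7. **Narrowed-interval analysis.** Silhouette-FD distributions
   concentrate in a narrow band just above 1. `fd_frequency_analysis`
   histograms the FDs per group and runs the ANOVA twice: on all values
   and on the closed interval [1.05, 1.09] (endpoints inclusive; a pure
   subset filter). Groups with no narrowed data are dropped with a
   logged warning.

## The synthetic generator

No image corpus accompanies the measurement design, so validation runs
on synthetic fields with exact ground truth. A field is a whitish canvas
with red nuclei (disks, radius ~22 px at the 512-px default) arranged
either on gland-ring contours or scattered ("disorganized"); benign
glandular fields get a green basal band rimming the ring. Dots are
rotated ellipses whose boundary radius is modulated as
`1 + a*sin(h*phi)` in the normalized elliptical frame: the axis ratio
sets roundness, the amplitude `a` (0–0.5) sets boundary ruggedness and
hence silhouette FD, with `h = 8` harmonics by default. Placement is
rejection-sampled with a hard non-overlap margin so the connected
components of the dot mask correspond one-to-one to ground-truth rows;
dots per nucleus are Poisson draws, and a nucleus that cannot fit all of
its drawn dots keeps its realized (recorded) count. Over-packed *nucleus*
layouts raise a `PackingError` instead of truncating. Composites are
4 x 6 grids of independently seeded tiles (24 merged high-magnification
fields) without stitching seams. Pixel noise is Gaussian (sd 4 grey
levels by default); pixel size defaults to 0.17 um/px (a typical 40x
objective with a standard microscope camera) and is configurable
everywhere — no computation hard-codes it.

The six-group default design encodes the qualitative contrast of
interest: carcinoma groups (Gleason patterns 2–5) get progressively more
elongated dots (axis ratio 1.45 → 1.60) with smoother boundaries
(ruggedness 0.12 → 0.06) in increasingly disorganized architecture;
benign groups (BNH, AAH) keep rounder (1.10, 1.15), more rugged
(0.30, 0.26) dots on gland rings with a basal band.

What the generator does **not** emulate: microscope optics and chromatic
aberration, stain variability between slides and labs, nuclear texture,
touching/overlapping dots, stitching artifacts, or true nucleolar
ultrastructure. Passing the recovery experiments therefore shows that
the chain measures what it claims on images obeying its appearance
model — not that the thresholds transfer to any particular scanner or
staining protocol unchanged.

## Replicated experiments and problem sizes

The cohort experiments run at reduced frame geometry (176-px frames,
4 nuclei of radius 20 px, 4-px dots) chosen so that every dot still
supports a silhouette-FD estimate while a 300-image cohort renders in a
couple of seconds:

* **FD parameter recovery** — 100 replicates of a 6 x 50-image cohort;
  pooled-carcinoma mean silhouette FD vs AAH and BNH by ANOVA + Tukey at
  alpha 0.01.
* **Null calibration** — 1000 cohorts of 6 x 4 images generated from one
  identical spec (disorganized, so rendering is label-blind); the
  six-group ANOVA's rejection rate at alpha 0.05 should sit near the
  nominal level.
* **Narrowed-interval contrast** — six FD samples with means spaced
  across [1.060, 1.080] (within-group sd 0.010, n = 50) plus one shared
  out-of-interval contamination sample (uniform on [1.10, 1.90], n = 150,
  identical across groups so it carries no group signal by
  construction); the narrowed ANOVA resolves the cores, the full-range
  ANOVA does not.

## Numerical choices and degenerate inputs

* Box-count fits require at least 3 sizes; empty masks are errors, not
  zeros. Counts use exact integer grid arithmetic on foreground
  coordinates.
* The order-k Sierpinski fixture is rasterized at `side / 2^k` px per
  cell; fits for it should start at the cell size (below it the set is
  locally two-dimensional and the slope biases upward). The shipped
  calibration uses sizes 4–128 for the order-7, side-512 triangle.
* Roundness needs >= 5 px (ellipse fit defined); below that it is NaN
  and the object is filtered.
* Eigenvalues are computed on the symmetric 2 x 2 covariance directly;
  ties (perfect circles) are handled by the `>= 1` convention.
* `skeleton_fd` returns the degenerate flag when the pruned skeleton has
  fewer than 8 px (e.g. a single dot).
* Determinism: every random draw flows from one
  `numpy.random.Generator`; cohorts spawn per-image seeds via
  `SeedSequence`. Identical spec + seed reproduces images, tables, and
  CSVs byte-for-byte.

## Known limitations

* The segmentation thresholds are calibrated to the synthetic appearance
  model; real slides need per-protocol threshold review (the config file
  exposes all of them).
* Sparse dot maps give skeleton FDs well below 1 at fine scales (a
  finite point set is zero-dimensional); the skeleton FD is informative
  at coarse scales and on dense fields, and degenerate cases are
  flagged.
* Nucleus segmentation from real images is out of scope: per-nucleus
  counts and compartment tags require a provided nucleus/compartment
  mask (synthetic ground truth or user annotation).
* The `total_normalized_area` scale (ppm of image area) is one of
  several possible normalizations; the basis is recorded in output and
  configurable, and absolute values are not comparable across
  normalization conventions.
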