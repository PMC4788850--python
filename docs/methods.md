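# Methods note

This note records the modeling assumptions, parameter choices and
numerical decisions behind palsykit, and what the synthetic generator
does and does not emulate.

## Model overview

The pipeline measures facial-paralysis severity as left/right asymmetry
of segmented facial features across five expressions (rest, eyebrow
raise, gentle eye closure, nose screwing, smile).  Its stages:

1. ROI detection (pluggable detector interface; no detector is bundled),
2. window-kernel initialization of an evolving curve per feature ROI,
3. localized active contour (LAC) segmentation,
4. integro-differential iris localization with eyelid clipping,
5. ten key points from the feature masks,
6. ten symmetry features f1..f10 in [0, 1],
7. hybrid rule + logistic cascade for screening and palsy-type
   classification, and regional + overall House-Brackmann grading.

Assumptions: near-frontal pose, one face per image, all five
expressions available, and features darker than the surrounding skin
after grayscale conversion (true of eyebrows, the iris, lips, and the
shadowed palpebral aperture).

## Parameters

All lengths are in pixels at roughly 960×720 working resolution; the
generator's stylized faces are 256×256 and use the same defaults.

### Preprocessing (`imaging`, `pipeline`)

- Median filter size 3 — speckle suppression with edge preservation.
- Full chain (median → histogram equalization → log transform with
  c = 0.1 on normalized intensities → rescale to [0, 255]) is
  implemented in `imaging.preprocess` and available via
  `PipelineConfig(preprocess_mode="full")`.  The pipeline default is
  `"median"`: histogram equalization is a rank transform that flattens
  any ROI histogram toward uniform, which provably drives the OTSU
  split toward the median pixel and, on low-texture ROIs, promotes
  amplified noise into large connected components.  Segmentation
  operates on median-filtered intensities by default for that reason.
- OTSU binarization maximizes between-class variance over all 256
  thresholds with the convention mask = (image ≥ t); dark-foreground
  polarity inverts the mask.  Components below 1% of ROI area are
  removed (8-connectivity).

### Curve initialization (`curve_init`)

- Left/right scans use a vertical all-ones kernel of height
  ⌈0.5 · blob height⌉; up/down scans a horizontal kernel of width
  ⌈0.5 · blob width⌉; minimum 3.  A kernel about half the blob's extent
  cannot report a spurious zero inside concavities, yet stays local
  enough to stop at the true boundary.
- Scans start at the largest surviving component's centroid and step one
  pixel at a time until the kernel-masked sum is zero; reaching the
  border first raises a convergence error, and the pipeline then
  enlarges the ROI by 4 and 8 px and retries (a blob clipped by a
  detector box has no zero-sum position inside it).

### Localized active contour (`lac`)

- λ (curvature weight): 0.3 for facial features, 0.1 for the iris.  The
  iris is small and nearly circular; a weaker length penalty preserves
  its scale.
- Localization-ball radius: 9 for facial features, 12 for the iris.
  The ball must span both sides of the boundary being refined; 9 px
  matches eyebrow/eyelid scale, 12 px the iris.
- Heaviside/Dirac smoothing width ε = 1.5: the transition band covers
  ±1.5 px so the narrow band is ~3 px wide.
- Time step: 0.45 / max|force| (CFL-style normalization), 100
  iterations.
- Signed-distance re-initialization every 10 iterations.  Updates only
  reach the narrow band, so the front can travel at most about ε pixels
  between re-initializations: a much longer period stalls the front far
  from the target, while re-initializing every step erases accumulated
  sub-pixel motion before a pixel can change sign.  Ten iterations
  balances the two; with ε = 1.5 the front covers typical
  initialization gaps well within the 100-iteration budget.
- The reported energy trace is evaluated on a freshly re-initialized
  unit-slope copy of φ so the Dirac band measure is comparable across
  iterations regardless of how steep φ has become.  The trace is
  non-increasing except for bounded transients at re-initialization
  steps.

### Iris localization (`iris`)

- Radius search range is configurable (pipeline default 7–16 at
  generator scale); internally one extra radius is sampled beyond each
  end so every in-range radius receives a central difference — a
  one-sided edge derivative would systematically favor circles at the
  range boundaries.
- Bright-pixel rejection at 200: any candidate whose perimeter touches a
  pixel above 200 is discarded (specular highlights produce strong but
  spurious radial gradients).
- Lower-arc integration (`min_sin = 0`): the upper iris boundary is
  routinely hidden by the eyelid; integrating only the lower arc removes
  its dilution of the radial derivative.
- `min_arc_fraction = 0.75`: candidates with most of their arc outside
  the image are rejected; a mean over a handful of border pixels is not
  the contour integral the operator maximizes and can win on pure noise.
- `center_polarity = "dark"`: candidate centers are restricted to the
  ROI's OTSU-dark pixels.  A true iris center lies in the dark iris; a
  small circle whose lower arc hugs the strong horizontal skin/eyelid
  edge can otherwise outscore a half-occluded iris, and its center
  always sits on bright skin.  Set `"any"` to search every position.
- Visible-iris mask: detected disc ∩ LAC mask of the open-eye region,
  then erosion + dilation with a disc of radius 2 to remove stragglers.

### Classification and grading (`classifier`)

- Rules come from a depth-3 decision tree (Gini, minimum leaf 3);
  leaves with purity ≥ 0.95 become rules, applied in decreasing purity
  then support order.  Stage rules fire before the logistic fallback.
- Fallback: L2 logistic regression, C selected from 10 log-spaced values
  in [1e-2, 1e2] by the harmonic mean of sensitivity and specificity.
- Protocol: stratified 70/30 holdout; on the 70% part, 20 repetitions of
  9-fold cross-validation; the selected model is refit on the full 70%
  and scored on the holdout.  When a class is rarer than the fold count,
  stratified folding is infeasible (every class must appear in every
  fold) and plain shuffled K-fold is used with per-fold exclusion of
  metrics whose class is absent.
- Regional graders use purity ≥ 0.98 rules and a multinomial logistic
  fallback with C = 1000: grade boundaries are steep steps of features
  living on [0, 1], so useful coefficients are O(100) and a strong
  penalty systematically underfits.
- The overall-grade lookup table (`data/hb_overall.json`) covers
  concordant regional triples (max − min ≤ 1) and is an editable
  interpretation of the House-Brackmann scale's regional descriptions;
  discordant triples go to the multinomial fallback.

## Synthetic generator: scope

`synthetic.render_face` draws stylized 256×256 grayscale faces:
uniform-intensity skin, eyebrow bands, elliptical palpebral apertures
containing circular irises clipped by an eyelid line, and an elliptical
mouth, antialiased by 2× supersampling, with mirrored pixel noise so a
zero-asymmetry face equals its own mirror exactly.  Expression tables
move the brows, eyelids, irises and mouth; a peripheral-palsy profile
attenuates brow, eye and mouth motion on the affected side and adds a
static lid droop and mouth sag, while a central profile attenuates mouth
motion only.  All facial features, including the sclera, are rendered
darker than skin so each feature binarizes as a single dark blob — the
polarity the initialization assumes.  A `motion_scale` field scales all
pixel-valued expression amplitudes so that a uniformly scaled spec is a
true similarity transform of the subject.

The generator emulates: controllable left/right asymmetry with the
forehead/eye sparing that distinguishes central from peripheral palsy,
partial iris occlusion, specular highlights, and pixel-exact ground
truth (masks, key points, iris circles, visible-iris areas, ROI boxes).

It does not emulate: pose variation, illumination gradients, skin
texture, hair, glasses, occlusions, non-elliptical eye shapes, or any
photometric property of real photographs.  Numbers computed on
synthetic cohorts characterize the implementation, not clinical
performance.

Tabular cohorts (`generate_cohort`) draw features from truncated
normals on (0, 1]: healthy mean 0.97 (sd 0.02) on f1..f9; peripheral
mean 0.80 (sd 0.08); central mean 0.95 (sd 0.02) on f1..f6 and 0.85
(sd 0.05) on the mouth features f7..f9.  f10 is the row mean.  Regional
grades follow a monotone step rule on regional means (thresholds 0.95,
0.875, 0.80, 0.70, 0.60).

## Problem sizes

The acceptance script's problem sizes (20 segmentation scenes, 25 eyes,
20 faces, a 65-subject cohort of 15 healthy / 40 peripheral / 10
central, a 240-subject grading cohort) are the package's own choices,
sized so the whole run finishes in well under a minute on one CPU while
keeping per-quantity sampling error visibly small.

## Limitations

- No face/ROI detector ships with the package; callers supply one (or
  manual boxes).  The synthetic registry detector exists for testing.
- The feature extractor assumes all five expressions; missing
  constituents are imputed at 1.0 (no asymmetry detected) with an
  explicit missingness flag — conservative for screening sensitivity.
- Rate-of-movement and area-ratio features compare quantities of a few
  pixels at small image scales, where single-pixel landmark quantization
  moves a ratio by several percent; the distance-ratio features are the
  scale-stable core.
- Overall-grade accuracy compounds three regional errors; on synthetic
  grading cohorts it is substantially below regional accuracy, as the
  acceptance script's output shows.
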