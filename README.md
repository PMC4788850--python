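# palsykit

Automated, photograph-based assessment of facial paralysis.

From five frontal photographs of a subject — at rest, raising the
eyebrows, closing the eyes gently, screwing up the nose, and smiling —
the package segments the eyebrows, eyes, visible irises and mouth,
extracts ten left/right symmetry features, screens for facial palsy,
distinguishes peripheral from central palsy, and assigns regional and
overall House-Brackmann severity grades.

## Method

**Segmentation.** Each facial feature is segmented with a localized
region-based active contour.  The contour is the zero level set of a
signed distance function φ (negative inside).  At each point *w* on the
curve, interior and exterior intensity means *u(w)*, *v(w)* are computed
inside a ball of radius *r* around *w*, and the curve moves to maximize
their separation:

    F(w) = −(u(w) − v(w))²,

with a curvature penalty weighted by λ.  Localizing the statistics lets
the model handle features whose contrast is only locally consistent
(e.g. an eye containing both bright sclera and dark iris).  The initial
curve is found automatically: OTSU binarization (dark foreground),
removal of components below 1% of the ROI area, then a window kernel
scanned outward from the blob centroid in four directions until its
masked sum reaches zero, yielding the blob's minimum bounding rectangle.

**Iris.** The iris circle maximizes the Daugman integro-differential
response — the Gaussian-smoothed radial derivative of the mean intensity
along a circular arc — over center and radius, with specular-highlight
rejection, lower-arc integration (the upper arc is routinely occluded by
the eyelid), and candidate centers restricted to dark pixels.  The
visible iris is the intersection of the detected disc with an active
contour of the open-eye region, cleaned by erosion and dilation.

**Features.** Ten features in [0, 1], each a min/max left-right ratio so
that 1 means perfect symmetry: iris-area ratios while raising the
eyebrows, smiling and screwing up the nose (f1, f7, f9); vertical
eye-landmark distance ratios across expressions (f4, f5, f6, f8);
eyebrow rate-of-movement ratios anchored at a reference point below the
eyes (f2, f3); and their mean (f10).

**Classification.** A two-stage hybrid cascade: high-precision rules
extracted from a depth-3 decision tree fire first; vectors matching no
rule fall through to an L2-regularized logistic regression.  Stage 1
screens healthy vs. unhealthy, stage 2 separates peripheral from central
palsy (central palsy spares the forehead and eyes).  Model selection
uses a stratified 70/30 holdout and 20 repetitions of 9-fold
cross-validation with the harmonic mean of sensitivity and specificity
as the criterion.  Grading trains one classifier per facial region
(forehead, eye, mouth); concordant regional-grade triples map to the
overall House-Brackmann grade through a shipped lookup table, and
discordant triples fall back to a multinomial logistic regression.

## Worked example

No clinical images ship with the package; a built-in generator renders
stylized frontal faces with controllable palsy profiles and records
pixel-exact ground truth.  The scripts in `examples/` each demonstrate
one capability.  `examples/segment_face.py` pushes a synthetic
peripheral-palsy subject (asymmetry 0.5, right side affected) through
the full pipeline:

```
$ python examples/segment_face.py
subject: peripheral palsy, asymmetry 0.5, affected side right
  f1: 0.737
  f2: 0.610
  f3: 0.613
  f4: 0.774
  f5: 0.839
  f6: 0.731
  f7: 0.742
  f8: 0.926
  f9: 0.777
  f10: 0.750
forehead/eye features (f1-f6) depressed, as expected for the profile
```

`examples/locate_iris.py` recovers a 40%-occluded iris with a specular
highlight:

```
$ python examples/locate_iris.py
true circle:      row=50 col=55 r=20
recovered circle: row=50 col=55 r=20
visible iris area: 783 px (62% of the full disc)
```

`examples/classify_cohort.py` and `examples/grade_subject.py` run the
classification protocol and the House-Brackmann grading.  A thin CLI
wraps the same library calls:

```
palsykit simulate cohort --out cohort.csv --seed 0
palsykit train --features cohort.csv --out model.json
```

## Layout

- `src/palsykit/imaging.py` — grayscale, preprocessing, integral images, OTSU
- `src/palsykit/curve_init.py` — window-kernel minimum-bounding-rectangle initialization
- `src/palsykit/lac.py` — localized active contour evolution
- `src/palsykit/iris.py` — integro-differential iris localization and clipping
- `src/palsykit/landmarks.py` — the ten facial key points
- `src/palsykit/features.py` — symmetry features f1..f10
- `src/palsykit/classifier.py` — hybrid cascade, model selection, H-B grading
- `src/palsykit/synthetic.py` — face renderer and tabular cohort generators
- `src/palsykit/pipeline.py` — end-to-end orchestration
- `docs/methods.md` — modeling assumptions and parameter rationale
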