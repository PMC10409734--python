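# Methods

`htoplan` implements a fully automatic planning chain for medial
opening-wedge high tibial osteotomy (HTO) on standing long-leg AP
radiographs, built around the Miniaci graphical construction. This note
documents the model behind each stage, the tunables that matter, what the
synthetic phantoms do and do not emulate, and the numerical choices made
where the design was open.

All geometry lives in image pixel coordinates: origin at the top-left
corner, x rightward, y **downward**. Angles are degrees. For a right leg
the medial direction is +x, for a left leg −x; models and landmark sets
carry an explicit laterality tag and the two sides are never mixed.

## The Miniaci construction

Given the named landmarks of one leg:

- **Mechanical axis (MA)** — femoral head center `F` to ankle joint
  center `A`.
- **Fujisawa point** — the load-bearing target on the tibial plateau,
  `Fu = M + 0.625 (L − M)` where `M`, `L` are the medial and lateral
  plateau edges (62.5% of the plateau width lateral to the medial edge).
- **Correction axis (CA)** — the ray from `F` through `Fu`, extended to
  the ground level `y = y_g`, meeting it at `G`.
- **Hinge point (HP)** — from the outer (lateral) knee point, shifted
  `0.14 W` along x toward the inner point and `0.18 W` downward, where
  `W = |x_outer − x_inner|` is the knee width.
- **Correction angle** `α` — the angle at HP between the rays `HP→A` and
  `HP→G`, computed with `atan2` of cross/dot products (never `arccos` of
  normalized dots, which loses precision near 0°). The sign convention
  makes α positive when the correction is valgus-producing, i.e. rotating
  the distal limb about HP by α carries the ankle center laterally onto
  the correction axis — the varus case an opening wedge treats. Reports
  print the magnitude plus a varus/valgus tag.

**Ground level.** The construction needs a "ground" row for `G`. The
default is the ankle-center level, which makes α exactly the rotation
about HP that maps `A` onto the CA; any fixed image row can be configured
instead (`geometry.ground_level`).

The construction is invariant under translations and uniform scalings of
all landmarks (with the ground row transformed alike) and equivariant
under mirroring with the laterality tag flipped; the test suite asserts
both to 1e-9°.

## Femoral head center — circular Hough transform

Edges of the head ROI come from a Canny detector (σ = 1.5 by default,
hysteresis thresholds auto-derived unless configured). The accumulator
then counts, for every candidate center `(a, b)` and integer radius `r`,
the edge pixels satisfying the circle equation within half a pixel,
`|√((x−a)² + (y−b)²) − r| ≤ ½`. This membership rule is implemented by
accumulating a precomputed annulus stencil per radius, which makes the
vote array *identical by construction* to the exhaustive
O(centers × edges) count — the suite verifies exact equality against an
independent brute-force triple loop on small fixtures.

The radius search is restricted to `[0.5, 1.0] × (min box side)/2`,
proportional to the detector's bounding box; the proportionality
constants are configuration (`hough.radius_c_lo/c_hi`) since a tight box
brackets the head diameter. Among hypotheses within 5% of the top vote
count, the winner is the one whose supporting edge gradients point most
directly at the center (mean |cos| between gradient and radial direction
— the classic gradient-direction peak criterion; polarity is ignored so
bright and dark disks behave alike), with ties broken by larger radius
then smaller y. The returned center is the vote-weighted centroid of the
3×3 accumulator neighborhood of the peak, giving sub-pixel precision
(≈0.1–0.4 px on phantoms). Detection fails loudly (with diagnostics)
when no hypothesis reaches `vote_floor` (default 0.3) of the circle
perimeter.

## Knee points — ASM and AAM

The inner (medial) and outer (lateral) plateau edge points are produced
by statistical shape models trained on annotated contours of 17, 31 or
59 landmarks; the two characteristic points sit at fixed indices recorded
in each model's index map. Separate models are trained per laterality.
All training and fitting happens on the knee ROI crop after global
histogram equalization (256 bins).

**Shape statistics.** Training shapes are brought to a common frame by
generalized Procrustes analysis (similarity transforms, mean renormalized
to zero centroid and unit size, rotational gauge fixed by aligning each
new mean to the previous one; convergence 1e-10 or 100 sweeps). PCA of
the aligned shape vectors retains the smallest number of modes covering
98% of variance (configurable). Mode coefficients are clamped to ±3√λ
during fitting — the standard plausibility constraint.

**ASM.** For each landmark, the model stores the mean and covariance of
the first-derivative intensity profile (length 2k+1, k = 6) sampled along
the shape normal and L1-normalized; covariances are regularized by
`ε = 1e-6·trace/dim` before inversion. Fitting alternates (a) moving each
landmark to the offset within ±6 px along its normal minimizing the
Mahalanobis distance to its profile statistics (ties resolved toward the
smaller offset) and (b) projecting the moved shape onto the model
subspace via a similarity pose fit plus clamped coefficients. Iteration
stops when the mean point movement falls below 0.1 px (40 iterations
cap). The stop threshold is deliberately small: the mean movement is
dominated by the ~60% of landmarks that settle within two or three
sweeps, and a looser 0.5 px stop fires while the two corner points — the
only ones the plan consumes — are still ~1.8 px off. A fit on an image
with no gradient evidence along the profiles is reported
`converged=False` rather than silently returning the initialization.

Landmarks on the shaft-side segments of the contour are tangentially
unobservable (the contour ends mid-edge on a featureless shaft), so
full-shape RMS may stall near 2 px while the corner points converge
sub-pixel; accuracy bounds are therefore stated on the knee points.

**AAM.** Texture is modelled in the shape-normalized frame: the mean
shape is scaled to a 64 px-wide reference frame, triangulated (Delaunay),
and every interior pixel's barycentric coordinates are precomputed so
that sampling a texture under any shape instance is a single bilinear
`map_coordinates` call. Textures are photometrically normalized (zero
mean, unit norm) and PCA'd at the same 98% retention. Parameters are
`[shape coefficients, a, b, tx, ty]` with the similarity pose
`x' = (1+a)x − by + tx, y' = bx + (1+a)y + ty` applied to the
reference-scaled base shape.

The parameter-update matrix is estimated numerically (regression of known
single-parameter perturbations against the texture residuals they
induce, pseudo-inverse with rcond 1e-8) rather than from an analytic
Jacobian — simpler, and adequate at these problem sizes. Perturbations
cover ±0.5σ and ±1σ per shape mode, ±0.03/±0.08 in the pose scale and
rotation terms, and ±2/±4/±6 px in translation.

Two numerical choices matter here:

- **Pre-smoothing.** Images are Gaussian-smoothed (σ = 4 px) before
  texture sampling, in training and fitting alike. Sharp boundary
  textures decorrelate within ~3 px, collapsing the linear update's
  capture range below the displacement the bounding-box initialization
  can produce; smoothing widens the basin to beyond 6 px while leaving
  the residual minimum at the true landmark position (recovery from 5 px
  off is ≈0.3–0.7 px on clean phantoms).
- **Step control.** Each iteration applies the predicted update scaled by
  the first factor in [1, ½, ¼, ⅛] that reduces the residual norm;
  convergence is declared on relative improvement < 1e-4, or when no
  factor improves but the smallest step leaves the residual within that
  tolerance (a flat minimum). Three consecutive iterations in which every
  factor makes things worse abort with `converged=False`.

**Initialization.** The mean shape is translated so its centroid sits at
the knee box center and scaled to 0.8 of the box width. Fitted landmarks
are clipped to the ROI expanded by 10% on each side.

On phantom suites the AAM yields smaller knee-point errors than the ASM
(medians ≈0.35 px vs ≈0.6–0.9 px), consistent with choosing the
appearance model as the production path (`shape.method: aam`); both
remain available.

## Talus border points — morphological segmentation

The tibiotalar joint space appears as a dark horizontal band between the
distal tibia and the talus. Segmentation: horizontal Sobel → absolute
response → threshold (Otsu unless fixed) → binary opening with a
horizontal 1×3 element → closing with a 7×7 square → removal of
components smaller than 0.1% of the ROI → keep the largest component
whose principal axis lies within 15° of horizontal.

Two structuring-element choices are deliberate. The band's edge response
is only ~2 rows thick, so an opening with a square element would erase it
— the 1×3 horizontal element removes specks while preserving thin
horizontal structures. And the band's top and bottom edge responses sit
`band_height − 1` rows apart, so the closing must be large enough to
bridge them into one component: 7×7 handles bands up to ~8 px tall (all
sizes are configuration).

The border points are the extreme columns of the selected band, each at
the vertical midline of the mask in that column; inner/outer assignment
follows laterality, and the ankle center is their midpoint (the package's
own reduction — the construction needs a center and the band's extremes
are symmetric about it). Rotation sensitivity is surfaced, not hidden: a
band whose principal axis deviates more than 5° from horizontal triggers
a `TalusRotationWarning`, and beyond 15° no band qualifies and detection
fails — rotated ankles are a documented failure mode of this stage.

## ROI ingestion and the phantom detector

Upstream detection is an ingestion contract: one text row per box
(`class cx cy w h [confidence]`, normalized to [0, 1]) in the darknet
dialect, with a mandatory class-id map. Boxes are grouped into per-leg
triples by the image midline (highest confidence wins within a side and
class); when at most one box of each class is present they are treated as
a single leg, since a centered single-leg image straddles the midline.
Objectness thresholding and non-maximum suppression are assumed done
upstream.

`phantom_detector` is a stand-in for a trained detector, valid only on
the stylized phantoms: it thresholds at the mid-intensity, splits bright
column clusters into legs, and reads the head (widest top band, box sized
from the diameter), knee (widest mid band) and ankle (two wide blocks
bracketing the dark band) off the vertical width profile. On clean
phantoms its boxes overlap truth with IoU ≥ 0.7.

## Synthetic phantoms

A phantom renders the structures each stage keys on: bright head disk,
femoral and tibial shafts, a plateau contour (shallow arc between the two
knee corner points with short descents down the tibial sides), and the
dark joint band between plafond and talus blocks, on a dark field
(intensities 0.85–0.95 bone vs 0.08 background, band 0.02). Noise models:
additive Gaussian (σ as a fraction of dynamic range) and salt pixels,
both seeded; rendering is bit-deterministic given the spec.

The deformity is parameterized by the *requested correction angle*: the
ankle center is placed by inverting the Miniaci construction (rotating
the HP→G ray medially by α and intersecting with the ground line), so
`correction_angle(truth) = α` holds to 1e-6° by construction and is
verified by an independent brute-force rotation search in the tests.
Requested angles are limited to [0°, 30°]; the default case-mix
distribution is a skew-normal (shape 4, location 4.5°, scale 5°,
rejection-truncated to the valid range), centered in the 4–18° window
where an osteotomy is typically indicated, with a right tail for severe
varus. Sampled anatomy jitters the head position/radius, knee level,
width (80–100 px), plateau curvature and talus width so shape-model
training sets carry genuine variation.

**What phantoms do not emulate** — and hence what passing tests do not
show about clinical data: real bone texture and trabecular structure,
soft-tissue and exposure gradients, osteophytes and deformed femoral
heads, implants, limb rotation out of the AP plane, and a trained
detector's box statistics. Results on phantoms are a correctness check
of the algorithmic chain under known truth, not a clinical validation;
the stated stage accuracies (head ≤1 px clean / ≤2 px at 10% noise, talus
≈1 px, knee points sub-pixel to ~1.5 px, end-to-end median ≤0.5° and
max ≤2° over seeded suites) are desk-scale analogues computed on these
phantoms at the problem sizes named in the tests (20–100 phantoms per
suite, chosen to keep the full suite under a minute of compute while
leaving the bounds statistically meaningful).

## Agreement statistics

Planned angles have no gold standard, so evaluation is agreement between
raters. The default ICC form is ICC(2,1) — two-way random effects,
single rater, absolute agreement — because the question is whether raters
(human or algorithmic) are interchangeable; other forms are selectable.
The implementation delegates to pingouin, and the tests pin it to the
explicit two-way ANOVA mean-squares formula to 1e-10 on random tables.
Note the sample estimator can fall below −1 on adversarial constructions
(e.g. a column and its negation); it is reported as computed. Tables with
no between-subject and no residual variance raise an undefined-ICC error.

Bland–Altman limits use exactly 1.96 standard deviations of the paired
differences (no small-sample t correction unless configured). Error
summaries are median/mean/min/max of absolute differences. Case-mix
distributions are fitted by maximum-likelihood skew-normal
(`scipy.stats.skewnorm.fit`); degenerate or non-convergent inputs raise.

## Known limitations

- The correction-angle sign convention assumes the standard AP
  orientation; images flipped left-right without a corrected laterality
  tag will yield mirrored signs.
- The ASM/AAM models are single-resolution; capture range comes from
  pre-smoothing rather than a pyramid, and inits more than ~8 px off the
  true knee position may not recover.
- Talus detection requires a near-horizontal joint band (warning at 5°,
  hard failure past 15°).
- No pixel-to-mm calibration is used anywhere; all outputs are angles and
  pixel coordinates, which is sufficient for the Miniaci angle but not
  for rules stated in millimetres (e.g. osteotomy starting-point
  placement, which is out of scope).
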