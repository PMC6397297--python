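# Methods

This note documents the models, defaults and numerical choices behind
`cytodose`, and what the synthetic benchmark does and does not establish
about real microscopy data.

## Synthetic populations

The generator emulates a heterogeneously transduced culture imaged by
widefield epifluorescence at ~20x.

**Expression.** Per-cell probe expression is drawn as
`10**Normal(gfp_log_mean, gfp_log_sd)` (defaults 3.0 and 1.5 in log10
units), i.e. a lognormal spanning several decades, reflecting the broad
per-cell uptake of viral vectors.  The lognormal shape is an assumption —
the underlying copy-number law is not known — but any heavy-tailed
multi-decade law gives the same analysis behaviour, since the pipeline
only uses expression ranks and log-scale statistics.

**Transfer functions.** Every controlled parameter responds to expression
through a piecewise transfer function: constant `baseline` below a lower
breakpoint `t1` (log10-expression), log-linear between `t1` and `t2`,
constant `plateau` above; continuous at both breakpoints.  Multiplicative
lognormal scatter with coefficient of variation `noise_cv` (median-one, so
geometric means are unbiased) models biological cell-to-cell variation.
Default breakpoints sit 1 and 2 decades above the median expression;
default responses: area 800 → 8000 µm² (cv 0.15), fibre count 4 → 24
(cv 0.20), fibre thickness 1.5 → 4.5 µm (cv 0.10), orientation coherence
0.30 → 0.90 (cv 0.05), aspect ratio 3.0 → 1.5 (cv 0.10), stellate
amplitude 0.15 → 0.05 (cv 0.20).  The plateau fibre count is capped so
that fibres remain resolvable structures rather than a continuous carpet
(above ~70% cell coverage the fibre/diffuse decomposition is ill-posed
for any method); saturated cells in culture likewise show thick but
disjointed fibres.

**Rendering.** Cells are star-convex polygons (radial cosine protrusions
drive the stellate factor; an affine stretch drives the aspect ratio) at
0.65 µm/px in a 256×256 px field; geometry that would leave the field is
redrawn up to 25 times, then errors.  The GFP channel is uniform inside
the cell with in-mask total equal to the drawn expression (proportionality
1 count per expression unit).  Fibres are capsules with Gaussian
cross-section (FWHM = drawn thickness, peak 300 counts) whose axial
orientations follow a von Mises law around a random cell axis; the
concentration is chosen so the mean resultant length of the doubled
angles equals the coherence ground truth.  A flat cytoplasmic stain level
(30 counts) and an elliptical DAPI nucleus (~12% of cell area, axes ratio
1.3) complete the field.

The *fibre amount* ground truth is the rendered fibre signal inside the
half-maximum footprint of each capsule.  A Gaussian profile carries ~24%
of its mass outside its FWHM; that skirt is indistinguishable from
diffuse signal and is booked as background, for the generator and the
measurement alike.

**Noise.** The default configuration renders noiselessly; the
`NoiseConfig.realistic()` preset adds a camera offset (100 counts), a
planar illumination ramp (50 counts peak-to-peak, random direction),
Poisson shot noise and Gaussian read noise (sd 5).  Noiseless defaults
are deliberate: with the per-pixel clipped background subtraction used
for total GFP, additive noise imposes a positive floor of roughly
`|mask| * sd / sqrt(2*pi)` counts per cell, which would mask the lowest
expression decades regardless of analysis quality.  The scatter that the
regime machinery must overcome — biological cell-to-cell variation via
`noise_cv` — is always on.

**What the benchmark does not show.** Synthetic cells are single,
non-touching, star-convex, with unstructured cytoplasm and ideal
registration.  Passing these tests demonstrates the correctness and
statistical calibration of the measurements, not robustness to clumped
cells, uneven staining, focus drift or debris; on real data the
segmentation steps (thresholds, ridge scales, background radius) are the
components most likely to need retuning.

## Fibre segmentation

Three steps inside the cell mask:

1. *Initial segmentation* — Sato tubeness filter at scales {1, 2, 4} px on
   the background-subtracted stain, thresholded by Otsu within the cell.
2. *Refinement* — each initial component's peak brightness is estimated as
   the median of a 3×3 local maximum along its skeleton (robust both to
   the skeleton sitting off the sub-pixel centreline and to intensity
   doubling at crossings); pixels within the background radius of a
   component are kept where the residual exceeds half that peak
   (half-maximum footprint).  Fragments with skeleton length < 10 px or a
   maximal inscribed radius < 1 px are removed.
3. *Background* — the diffuse signal is a grey-scale opening with a disk
   of radius 12 px (larger than the widest default fibre); outside-cell
   pixels are pre-filled with the in-cell median so the opening does not
   erode at the cell border.  Fibre brightness is the clipped residual on
   the fibre mask.

Local orientation is the minor eigen-direction of the structure tensor
(sigma 2 px), i.e. along the ridge.  All circular statistics double the
angles because fibres are axial (undirected); angle 0 is the image x-axis
(columns), range [0, π).

Descriptor formulas: area = |mask|·ps²; aspect ratio = major/minor axis of
the moment ellipse; stellate factor = Crofton perimeter over convex-hull
perimeter, minus 1; fibre amount = Σ fibre brightness; thickness = 2 ×
mean distance-transform value on the skeleton; length = mean per-component
skeleton length (diagonal steps √2); orientation coherence =
brightness-weighted resultant length of doubled orientations; radiality =
brightness-weighted mean cos² of the angle to the radial direction from
the cell centroid.  An empty fibre mask reports the fibre descriptors as
0 with `has_fibres=False`.

Known limitation: in extreme saturation (fibres covering > ~60% of the
cell) the opening absorbs part of the overlapped fibre signal, so absolute
fibre amount is under-recovered there; the effect is approximately
constant across the plateau and does not disturb regime detection.

## Dose-response curves and regime detection

Cells with positive expression (and, for geometric pooling, positive
descriptor values) are sorted by total GFP and cut into `len // n_min`
consecutive equal-count bins (`n_min` defaults to 100; smaller values are
appropriate for scarcer measurements).  Pooling per descriptor: geometric
mean with geometric-SD band for multiplicative quantities (area, fibre
amount, length), arithmetic mean ± SD for bounded/symmetric ones
(thickness, stellate factor, coherence), median with Q1–Q3 for aspect
ratio and radiality.

The ratio of variances at interior bin *i* uses two flanking windows of
`N` bins (default 3) with sample variances (denominator N−1), computed on
log-transformed bin statistics for positive-valued descriptors.  A zero
trailing variance flags the point as undefined rather than infinite.

**Peak detection.** The raw RoV of small windows is F(N−1, N−1)
distributed under the null — so heavy-tailed that perfectly flat noisy
curves routinely produce |log RoV| of 3–5.  Candidate transitions are
therefore scored on a stabilised statistic: both window variances are
damped by the 0.35 quantile of all window variances of the curve (a
noise-floor estimate that tolerates up to ~2/3 of the curve being
trend-dominated), the log ratio is smoothed with a centred 3-bin mean,
and local maxima of its magnitude above 3.0 (natural-log units) become
candidates — at most the two largest, ordered by expression.  The
threshold was calibrated on simulated flat and two-regime curves (null
99th percentile 1.84–2.16 versus signal 1st percentile ≥ 4.5 across the
regularisation choices examined), leaving a wide margin on both sides.
A variance *rise* ("up") marks the dose-response onset, a *collapse*
("down") the saturation onset.

Global thresholds pool candidates across descriptors: G1 is the geometric
mean of all "up" candidates, G2 of all "down" candidates (geometric,
because expression spans decades); crossed or one-sided candidate sets
are errors.  Cells are labelled by half-open intervals: [0, G1) no-effect,
[G1, G2) dose-response, [G2, ∞) saturation.

## Time-lapse metrics

Centroids are tracked per frame (threshold, hole-fill, largest component,
intensity-weighted centroid; a mask-centroid flag exists) with linear
interpolation across at most 2 consecutive empty frames.  Migration
directionality is net displacement over total path length; it is
undefined (NaN) for a zero-length path.  Synthetic tracks are persistent
random walks with wrapped-normal turning angles whose mean resultant
length equals the persistence parameter (σ = √(−2 ln p)), sampled at
10-min intervals for 18 h by default.  F-actin interframe change and
disassembly follow the percent formulas given in the README; the
per-cell summary of interframe change uses the mean absolute value,
since signed changes average towards zero for any near-stationary
series.

## Scales used by the automated checks

The test suite and `scripts/acceptance.py` use: 100 seeded 40-bin curves
(4000 cells each, scatter cv 0.05) for breakpoint-recovery and
null-rejection rates; one rendered population of 1000 cells in 256×256 px
fields (analysis with n_min 20, i.e. 50 bins) for end-to-end threshold
and label recovery; small noiseless populations for morphometric,
enrichment and colocalization fidelity; 1000 random tracks and a
10-level × 100-track grid for the migration-statistic properties.  These
sizes keep the full suite within a few minutes on one CPU while leaving
the statistical margins described above.
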