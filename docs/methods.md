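# Methods

This note documents the models and procedures implemented in `sceneaffect`,
the numerical choices behind them, what the synthetic-data generators do and
do not emulate, and the known limitations.

## Contour geometry

A line drawing is a set of open polylines ("contours") of fiducial points on
a pixel canvas (origin top-left, y down). All downstream features derive
from four per-contour quantities:

- **segment orientation** — the counter-clockwise angle from horizontal in
  *visual* space, computed from `(dx, -dy)` because the canvas y axis points
  down, reduced modulo 180°. Reversing a contour leaves orientations
  unchanged.
- **contour length** — the sum of Euclidean segment lengths, in pixels.
- **vertex angularity** — at each interior vertex, the absolute turn angle
  between the incoming and outgoing segment directions (0–180°) divided by
  a length scale built from the two adjacent segments, in degrees/pixel.
  The divisor is the **mean** of the two adjacent segment lengths by
  default ("min" and "sum" are available). The mean is symmetric under
  contour reversal and gives a natural deg/px unit; the turn is unsigned
  because the sign of a bend carries no information for the smooth-vs-sharp
  distinction the feature encodes.
- **folded mean orientation** — each orientation folded from [0°, 180°)
  onto [0°, 90°] (so 180° ≡ 0°) and averaged, weighted by segment pixel
  length by default. Folding is onto a quarter turn rather than all the way
  to a single axis because the stimulus design distinguishes horizontal
  from vertical contours.

Two-point contours have no interior vertex and an empty angularity list;
their histogram treatment is defined below.

## Feature histograms

Each drawing is summarised by three 8-bin, pixel-weighted histograms. Bin
centers are fixed constants of the method:

| feature     | centers | units |
|-------------|---------|-------|
| orientation | 0, 22.5, …, 157.5 | degrees |
| length      | 1.66, 4.47, 12.02, 32.36, 87.10, 232.42, 630.96, 1698.24 | pixels |
| angularity  | 1.38, 2.63, 5.13, 9.77, 18.62, 35.48, 67.61, 131.83 | deg/px |

Length and angularity centers are evenly spaced in log10 and are treated as
verbatim constants; recomputing them from the nominal 1–2789 px range gives
slightly different values (≈1.64, 4.43, …), so the printed constants win.

Mass assignment uses triangular (linear) interpolation between the two
adjacent centers — circularly for orientation (157.5° wraps toward 0°), in
log10 domain for length and angularity, with values beyond the extreme
centers clamped onto the end bins. A nearest-center mode exists for
comparison; the two agree exactly when all values sit on centers.
Interpolation was chosen over hard assignment to avoid quantisation cliffs
in the generated-stimulus classification; the conservation property below
holds under both.

Contributions:

- orientation: each *segment* contributes its pixel length at its
  orientation;
- length: each *contour* contributes its total length at log10(length);
- angularity: each *interior vertex* contributes half of each neighbouring
  segment (so a segment's two halves go to its two end vertices). The
  half-segments at contour endpoints, entire 2-point contours, and vertices
  whose turn is exactly zero carry no turn information and are assigned to
  the lowest bin (the zero-turn class).

With these rules each histogram's total mass equals the drawing's total
contour length in pixels (tested to 1e-6 relative). Weights are continuous
pixel lengths, not integer pixel counts: contours are continuous polylines
and "pixels of contour" is read as contour length in pixel units.

The regression feature vector concatenates Orientation 1–8, Length 1–7 and
Angularity 1–8 (23 predictors). The top length bin is dropped because
contours that long are too rare to estimate. An element-wise square root is
applied by default to tame the long-tailed pixel masses. The vector keeps
all 23 entries; any collinearity in a particular sample is handled at fit
time (below), which keeps behaviour deterministic whatever the achieved
rank.

## Valence regression

Mean valence ratings (1–9 Likert) are regressed on the 23 features by OLS
with an intercept (`ValenceRegression`, delegating inference to
statsmodels). Before fitting, columns that are numerically linear
combinations of earlier-pivoted columns (pivoted QR on the centered design,
relative tolerance 1e-8) are removed and reported by name; fitted values
are then invariant to duplicated or constant columns. p-values are
two-sided from the t distribution, with no multiple-testing correction.
Added-variable (partial-regression) series are computed by residualising
the predictor and the response on the remaining predictors; the slope of
that pair equals the multiple-regression coefficient (Frisch–Waugh),
asserted numerically in the tests. Close/far subset fits are independent
OLS runs per label; a subset with too few rows yields a reported error
without blocking the other.

## Stimulus generation

Contours harvested from full-size (800×600) drawings are classified into a
2×3×4 factorial — Length (short/long) × Angularity (low/medium/high) ×
Orientation (horizontal/vertical/both/diagonal). The continuous-to-class
cut values are parameters (`BinThresholds`); the defaults reuse the
histogram bin geometry rather than introducing new constants:

- length split 87.10 px (a log-scale center near the middle of the range);
- angularity splits 5.13 and 35.48 deg/px (log-scale centers);
- orientation band 22.5° (the histogram bin half-spacing): folded mean
  below 22.5° → horizontal, above 67.5° → vertical; otherwise the contour
  is "both" when more than half of its pixel length lies within the band
  of 0° or 90°, else "diagonal".

Image assembly: contours are sampled uniformly from one bin — without
replacement within an image, with replacement across images — scaled down
by 4 (so an 800×600 source always maps into the 200×150 canvas; e.g. a
start point at [400, 300] lands at [100, 75]), shifted by the minimal
offset when a smaller canvas or scale would leave points outside, and
truncated from the tail end (whole points) if the bounding box cannot fit
at all. A contour reduced below 2 points is skipped and another drawn.
Contours are appended until the summed *placed* length exceeds the 1000-px
budget; 20 images per bin give the 480-image set. Bin membership is
assessed before placement; shortening can in principle drift the realized
features, and the per-image provenance records every adjustment.

## Choice model

Each 4AFC trial yields exactly two binary observations: the image chosen
most positive/safe (outcome 1) and most negative/threatening (outcome 0);
the two neutral images are discarded. The model is a logistic regression
with the full Length × Angularity × Orientation factorial as fixed effects
and a Gaussian random intercept per participant:

    logit P(y = 1) = x'β + b_i,   b_i ~ N(0, σ²).

Factors are sum-to-zero coded with levels in alphabetical order, which
makes the likelihood-ratio test of each effect — refitting without that
effect's columns while retaining all others — a Type-III-style test that
remains meaningful for main effects in the presence of interactions.
χ² = 2(LL_full − LL_reduced) with df equal to the columns removed.

Numerics: the marginal likelihood uses the Laplace approximation. Rather
than running a quasi-Newton search over (β, log σ) jointly, β and the
random intercepts are profiled out at the joint penalized mode (Newton
iterations with Schur elimination of the diagonal per-group block and step
halving), leaving a one-dimensional bounded search over log σ. This is the
same profiling scheme lme4 uses for its fast GLMM path; it needs an order
of magnitude fewer likelihood evaluations than a 25-parameter quasi-Newton
and no gradient approximations. Observations sharing a participant and
design cell are aggregated to binomial counts first, so a fit costs the
same whether a participant contributes 240 or 24,000 rows.
Log-likelihoods use the Bernoulli convention (no binomial coefficient), so
they are directly comparable to a plain logistic regression on the raw
rows; the fitted Laplace likelihood is never below the σ=0 logistic
likelihood, and the σ=0 solution is returned when the scalar search ends
at the boundary. In the tests the fit is cross-checked against statsmodels
`Logit` (σ=0 data) and an independent 40-node Gauss–Hermite evaluation of
the marginal likelihood.

An optional `participant+trial` random structure adds an intercept per
trial nested in participant (two-level Schur elimination, 2-D scalar
search). It is off by default: with exactly one positive and one negative
outcome per trial, the trial intercept is only weakly identified, and in
simulations its estimate collapses toward zero.

Convergence: inner Newton stops at relative penalized-likelihood change
below 1e-11 (error with trace after 200 iterations); the outer search is
bounded to σ ∈ [1e-3, 5]. Apparent separation in the fixed structure
(|β| > 30 or a non-converging start fit) triggers a warning and a small
ridge (1e-4) on the starting values, flagged on the fit object.

## Synthetic data

The generators define the study conditions used throughout the tests.

**Contours** are zig-zag walks: headings alternate around a base direction
(0° horizontal, 90° vertical, 45°/135° diagonal, strict 0/90 alternation
for "both") with turn amplitude and segment scale chosen per angularity
class so the realized mean angularity lands inside its class (e.g. 12°
turns over 10-px segments ≈ 1.2 deg/px for "low"; 30° turns over 0.6-px
segments ≈ 50 deg/px for "high"). Segment lengths are jittered and then
rescaled so the total equals the sampled target exactly (short: 45–70 px,
long: 150–300 px, straddling the 87.10-px split with margin). Under the
default thresholds the realized classification matches the intended bin in
>99% of draws (tested). Pools pack 24×n contours into 800×600 drawings so
the ÷4 placement path is exercised end to end.

**Rating datasets** add free-form "speck" contours (1–4 random-heading
segments, lengths ~1.6–16 px) to each drawing so that *all* 23 features,
including the shortest-length and sharpest-angularity bins, vary across
images. Ratings are `clip(5 + (X − mean(X))·β* + N(0, σ), 1, 9)` on the
square-root feature matrix. The columns are centered before applying β* so
the ratings stay at mid-scale; slopes are unaffected and the clipping
fraction (reported on the output) stays at zero under the default β*,
which places small effects on the vertical-orientation, long-length and
high-angularity features (−0.03, +0.01, −0.08), the three cues the rating
analysis is designed to detect.

**Choice sessions**: each simulated participant partitions the 480 images
into 120 four-image trials (each image exactly once). The default decision
rule adds standard Gumbel noise to additive cell utilities and picks the
argmax/argmin as the positive/negative choice — a standard discrete-choice
device under which the GLMM is misspecified but directionally consistent,
as in the real experiment. Exact-recovery tests instead use the
`bernoulli` rule, which draws each binary outcome directly from the
random-intercept logistic model, so the GLMM is correctly specified and
estimates can be compared to truth (±0.1 at 157 participants, SD 0.5).
Default utilities sum to zero within each factor (long +0.4 / short −0.4;
low +0.5 / medium 0 / high −0.5; horizontal +0.6 / others −0.2), matching
the qualitative direction long–smooth–horizontal → positive/safe; a
threat-task preset makes Length the strongest cue.

What the generators do **not** emulate: semantic content and its
correlation with features, artists' tracing styles, response times,
omitted/invalid responses (the readers drop and count them, but the
generators never produce them), and the dependence between the high and
low picks within a trial beyond what the Gumbel rule induces. Passing
recovery tests therefore show the estimators are correct and calibrated on
data from the assumed models, not that the models are true of human data.

## Problem sizes in the test suite

The acceptance tests run the study-scale conditions: 1182 rating images
with 200 recovery and 500 null replicates; 157 participants and 480 images
per choice-session replicate (20 replicates for recovery, 20 seeds
end-to-end); LRT calibration uses 200 replicates of a reduced design (24
participants × 240 observations), a size at which the χ² reference is
already accurate. The binomial aggregation above is what keeps full-scale
GLMM fits below a second each.

## Known limitations

- The package does not ship the access-restricted IAPS tracings or any
  human judgement data, so published human-study statistics (rating-model
  F/R²/β values, choice-model χ² values) are not recomputed here; applying
  the pipeline to such data is the natural external check.
- The Laplace approximation with profiled β (the fast-glmer scheme) can
  differ slightly from full Laplace maximisation for very small clusters;
  with 240-observation clusters the difference is far below the reported
  precision.
- `classify_contour`'s defaults are method parameters, not measured
  constants; analyses of real tracings should report them.
- SVG import is deliberately restricted to straight-line geometry; curved
  tracings must be polygonised upstream.
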