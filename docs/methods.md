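# Methods

`budscreen` implements a morphometric discovery procedure for immunostained
tumor sections: binarize each image, outline and measure every stained
particle, select particle subsets with circularity and size filters, and
screen every subset's features for association with distant-metastasis
outcome. This note records the models, estimators, defaults and numerical
choices, and what the synthetic data can and cannot show.

## Imaging

Images are reduced to 8-bit grayscale (RGB via 0.299R + 0.587G + 0.114B,
rounded). The stain is dark on a light background, so a binarization
threshold `T` marks pixels in `[0, T]` (inclusive) as foreground. Fixed
batch thresholds are 220, 240 and 250; the automatic threshold is iterative
intermeans (IsoData) on the intensity histogram — iterate
`T <- round((mean(I<=T) + mean(I>T))/2)` to a fixed point — which is the
default automatic method of the common particle-analysis software. A
constant image has no valley and raises an error. Because foreground is
`[0, T]`, masks nest: the 250 mask always contains the 220 mask.

## Particle measurement

Particles are 8-connected components (4-connectivity available). Per
particle: pixel area (interior holes are background and not counted),
outer-boundary perimeter, circularity `4*pi*area/perimeter^2` capped at 1,
maximum Feret (caliper) diameter, convex-hull area, and solidity
`area/hull_area` capped at 1. Holes are filled only for boundary tracing;
edge-touching particles are included.

**Perimeter.** The estimator is chain-code based on the Moore-traced outer
boundary (pixel centres). Purely rectilinear boundaries (no diagonal steps)
get exact crack-geometry length: unit steps plus a signed miter corner term
`sum(+-min(tan(|turn|/2), 2))`, reproducing `2(W+H)` for a W x H rectangle,
202 for a 100 x 1 strip, and the end-caps of 1-px-wide lines. Curved
boundaries use corner-corrected weights `P = 1.0374*Ne + 1.3702*No -
0.1288*Nc + 2.8316` (`Ne`/`No` axis/diagonal steps, `Nc` direction
changes); the constants were calibrated by least squares on randomly placed
digital disks of radius 9-45, and the intercept absorbs the fixed total
curvature of a closed convex boundary. Worst-case error on digital disks of
radius >= 10 is ~1.2%, on digital ellipses < 1%, and axis-aligned
rectangles are exact. A naive crack-boundary perimeter was rejected because
it overestimates a disk's perimeter by ~27% (circularity ~0.62), which
would empty the 0.8-1.0 circularity band that the screening relies on. A
single-pixel particle is assigned perimeter pi (the digitization of a dot
of radius 1/2), making its raw circularity exceed 1, hence the cap — small
round particles therefore saturate at circularity 1.0, which is what lets
them pass the 0.8 filter robustly.

**Hull, solidity, Feret.** The Feret diameter is the exhaustive pairwise
maximum over the convex hull of the full pixel-corner points (a single
pixel measures sqrt(2); a 10 x 5 rectangle sqrt(125)). The hull *area* uses
corner points pulled in by 0.25 px on curved boundaries — calibrated so
digital-disk hull areas track the continuous `pi r^2` within ~1% and disk
solidity stays >= 0.98 — and the full corners on rectilinear boundaries
(rectangles exact). The two polygons differ deliberately: the caliper
diameter is a corner-to-corner quantity, while the hull area of a digitized
curved shape is systematically overestimated by full corners (+4-6% for
disks). Consequence: very small polyomino shapes (e.g. the 5-pixel plus,
which is equally a digitization of a disk of radius ~1.3) get a hull
smaller than their corner polygon and their solidity caps at 1; solidity is
a meaningful descriptor only for particles some 10 px across and larger.

**Filters.** A filter is (binarization, circularity range, size range);
size means area in pixels (the analyzer's uncalibrated convention; 20 px ~
7 um equivalent diameter at 1.4 um/px). All bounds are inclusive. The
default grid is 4 binarizations (auto, 220, 240, 250) x 5 circularity
minima (0, 0.2, 0.4, 0.6, 0.8) x 4 size minima (10, 20, 50, 100) = 80
subsets.

## Features and aggregation

Per image and filter subset: particle count, total area, average size
(total/count), mean circularity, mean solidity. A zero-particle image
contributes 0 to the size features but *missing* to the shape means (a mean
shape of an empty set is not zero); patient vectors are arithmetic means
over the patient's images, skipping missing entries, and a patient whose
shape feature is missing in every image is excluded pairwise from that
feature's evaluation. Evaluation order and patient order never affect
results.

## Prognostic statistics

* **AUC** is Mann-Whitney with midrank ties; orientation is never flipped
  (AUC < 0.5 marks low-risk association). The p-value is the tie-corrected
  normal approximation; the CI uses the Hanley-McNeil variance at the
  observed AUC.
* **Optimism correction** is the Harrell bootstrap: resample patients
  (stratified by event status so resamples keep both classes), re-derive
  the rule on the resample, and subtract the mean resample-vs-original
  performance gap from the apparent estimate; B = 1000 by default, seeded.
  For the AUC the rule is the identity, so the correction reduces to
  `2*AUC - mean(AUC_b)`, which is vectorized over resamples so the 400-record
  grid can afford it.
* **Optimal cutpoint** maximizes the two-sample log-rank chi-square over
  every midpoint between adjacent distinct feature values whose split
  leaves each group at least 10% of patients (configurable); ties break
  toward the more balanced split, then the smaller cutpoint. The selection
  is re-run inside each bootstrap resample rather than applying a
  multiple-testing correction to the reported p-values. The log-rank
  statistic is computed vectorized across all candidate cutpoints and is
  cross-checked against lifelines in the tests.
* **Cox regression** maximizes the Breslow-ties partial likelihood
  (statsmodels PHReg) with Wald intervals; monotone-likelihood fits
  (perfect separation — e.g. a dichotomized feature whose low group has no
  events) are detected by exploding coefficients/standard errors and
  reported as failures rather than numbers. Backward elimination enters
  candidates at univariate p <= 0.2 and repeatedly drops the largest
  p >= 0.05 (ties drop the later-listed). A Schoenfeld-residual
  proportional-hazards diagnostic is available but never gates results.
* **Median follow-up** is the reverse Kaplan-Meier: invert the event
  indicator and report the first time the censoring survivor function
  reaches 0.5.
* **ROC sample size** is the Hanley-McNeil search: smallest `n_pos` with
  `z_{a/2}*SE0 + z_b*SE1 <= AUC_alt - 0.5` (null variance at AUC 0.5,
  alternative at `AUC_alt`, `Q1 = t/(2-t)`, `Q2 = 2t^2/(1+t)`). At alpha
  0.05, power 0.80, AUC 0.72 and 4 negatives per positive this returns 17
  positives / 85 patients.

## Screening

`SubsetScreen` (model) / `ScreenResults` (results): each image is
binarized, labeled and measured once per binarization (a content-keyed
cache also recognises identical masks across binarization settings), then
every filter subset reuses those measurements — measure once, filter many.
Every (subset, feature) record gets a corrected AUC and an
optimal-cutpoint Cox fit; records are ranked by `|corrected AUC - 0.5|`, so
low-risk features compete equally. Records whose feature is missing for
more than half the patients are flagged and excluded from ranking. No
multiple-testing correction is applied across the 400 records (a
supplementary Bonferroni flag is reported per record). Per-record
bootstrap streams derive from `(seed, record index)`, so results are
independent of patient or evaluation order. `size_profile` evaluates the
count feature in half-open particle-size windows `[lo, hi)` and reports
the AUC and particle tally per window.

## Synthetic data

The generator stands in for the unavailable patient cohort, with the
statistical structure the analysis assumes.

**Images** (1.4 um/px, default 176 x 176 px, 8-bit): background normal
around 253 clipped to stay strictly above 250, all stain intensities below
180, objects separated by >= 1 px so 8-connected labeling preserves
rendered counts. Four object classes:

* *single cells* — hard disks (no anti-aliasing, so every threshold
  segments them identically) with target areas uniform on a per-patient
  band within 20-60 px (see cohorts);
* *clusters* — unions of 10-50 disks (radius 2-5 px) along a random walk
  of stride 3-7 px: irregular, low-circularity sheets. A small fraction
  (~2-5%) of short walks comes out compact enough to pass the 0.8
  circularity filter, mirroring the occasional larger-than-cell particle
  in real optimal subsets;
* *specks* — round debris of 1-13 px whose capped circularity passes any
  shape filter; only the size filter removes them;
* *fragments* — chains of small disks: small ones (below 20 px, any
  circularity) and large elongated ones (20-50 px, circularity ~0.3-0.75).
  A per-patient elongation factor scales the chain stride, so mean
  fragment shape varies patient-wide (staining-fragmentation morphology).

Debris placement is best-effort: when a junk-rate draw exceeds what the
canvas can hold, placement stops at saturation and the ground truth
records the rendered counts; cells and clusters are strict (a cohort
image that cannot hold its cells is an error, and cells are placed first).

**Cohorts** (defaults 102 patients, exactly 20 events, 5 images each):

* The per-patient latent log mean single-cell count is Gaussian with
  standardized event/non-event separation `d` (default `d` such that
  `Phi(d/sqrt 2) = 0.82`); because AUC is invariant under monotone
  transforms, the latent count's generating AUC is exactly `Phi(d/sqrt 2)`
  regardless of the log-normal scale (sd 0.35; baseline mean 6 cells per
  image — the prognostic particles are *scattered* single cells, sparse by
  nature). Per-image counts are negative binomial (size 20) around the
  latent mean; this within-patient noise attenuates the *measured*
  mean-count AUC to roughly 0.78-0.80 at the default settings.
* Cluster, speck and fragment rates are per-patient log-normal (log-sd
  1.0, outcome-independent) with per-image Poisson counts: tumors differ
  enormously in epithelial content and staining debris, which is what
  makes the unfiltered and mid-circularity subsets noisy and the filtered
  single-cell subset informative.
* Each patient has a cell-size centre drawn uniformly on 26-54 px (areas
  uniform +-10 around it, clipped to 20-60): a staining/sectioning scale
  that adds patient-level noise to area-based features but not to the
  count — the reason a count is the more robust marker than stained area.
* Event times are exponential with log-rate linear in the latent density
  (slope 0.5 per latent SD, scale chosen so the median time to metastasis
  is ~60 months, clipped to 6-160); non-event follow-up is uniform on
  77-165 months, matching the study's follow-up window. Proportional
  hazards holds by construction, so Cox recovery is well-posed.
* Clinicopathological covariates (age, tumor size, grade, ER, PR) are
  drawn around the study's published distributions and are independent of
  outcome by default.

**What passing tests show — and what they do not.** The synthetic images
are caricatures: hard-edged objects, no anti-aliasing, no partial staining,
no touching cells, no illumination gradients, a single stain channel.
Passing the recovery tests shows the *pipeline* is correct (segmentation,
measurement, filtering, aggregation, ranking and validation machinery
behave as specified under a known generating model); it does not show that
real tumor sections carry the planted signal, nor that the specific
estimated effect sizes transfer. Between-image dispersion of features is
not reported in the source study, so the dispersion defaults here are free
modelling choices, not data-derived.

## Problem sizes and runtime choices

The full-size recovery experiments run 25 replicates of 102 patients x 5
images at 176 x 176 px with B = 300 bootstrap resamples per record (the
default B = 1000 is used for single evaluations); these sizes keep a full
replicate near half a minute on one CPU while leaving the Monte-Carlo
error of a corrected AUC near +-0.01. Determinism: every generator and
every bootstrap takes an explicit seed; two runs with the same seed are
bit-identical.

## Known limitations

* Watershed splitting of touching particles is not implemented; the
  generator keeps objects disjoint, real sections do not.
* The stain-decomposition step of the original workflow is replaced by
  luminance conversion / single-channel input.
* Perimeter (hence circularity) for particles under ~8 px across is
  convention, not measurement: such particles saturate at circularity 1.
* Solidity's hull is accuracy-calibrated for curved shapes >= 10 px
  across; for tiny polyominoes the hull can be smaller than the pixel
  count and solidity caps at 1.
* The optimism bootstrap corrects the AUC; the reported Cox hazard ratios
  are apparent (cutpoint re-selection inside resamples is available for
  the AUC ranking, and uncorrected log-rank p-values from maximally
  selected cutpoints are anti-conservative by construction).
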