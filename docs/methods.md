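# Methods

## Scope and design

`sitefold` studies how site-specific, non-biologic image variation (batch
effect) inflates cross-validated accuracy in multi-site histology cohorts,
and how confining each tissue-submitting site to a single fold removes the
inflation. Everything runs at desk scale on synthetic data: the package
contains no network-trained models and downloads nothing. Where a
full-scale study would train a convolutional network on whole-slide images,
`sitefold` uses a 20-value hand-crafted tile signature and a random-forest
scorer as a surrogate; the statistical machinery around it (fold
optimization, AUROC evaluation, bootstrap, t-tests, FDR) is the real
subject and is implemented exactly.

## Image features

The site signature of an image is 15 first-order values — per RGB channel
the mean, population standard deviation, skewness `m3/m2^(3/2)`, kurtosis
`m4/m2²` (central moments with 1/N normalization), and Shannon entropy of
the 256-bin intensity histogram in nats with `0·log 0 := 0` — plus 5
second-order Haralick features of the gray-level co-occurrence matrix
(GLCM): contrast, dissimilarity, homogeneity, angular second moment, and
correlation.

GLCM conventions: 256 gray levels, non-symmetric ordered pairs
(reference → neighbor), distance 1, counts normalized to sum 1, luminance
via ITU-R 601 weights (0.299, 0.587, 0.114) rounded to the nearest
integer. Features are averaged over the four standard angles (0°, 45°,
90°, 135°), which makes them invariant under 90° image rotation. Whether
texture should be computed on luminance or per channel is a genuine
choice; luminance is used here because the texture of interest
(nuclear-density patterns) is a brightness phenomenon, and channel color
information is already carried by the first-order block.

Degenerate-input conventions, chosen to avoid silent NaN propagation:
skewness and kurtosis of a zero-variance sample are reported as NaN (an
explicit undefined marker, never an exception); the GLCM correlation of a
constant image is defined as 1; ANOVA with zero within-group and
zero between-group variance reports NaN, with positive between-group
variance +inf.

Slide-level statistics are computed at 5 µm/px (area-average resampling);
deep-learning-style tiles are cut at 299 px spanning 302 µm (bilinear
resampling for the near-unity rescale), on a 0-based, (row, col),
half-open grid. Tiles whose mean grayscale intensity exceeds 230 are
treated as background and dropped; the ROI-inclusion rule is
fully-inside (a tile is kept only if its whole area lies in the mask),
both configurable.

## Stain operations

* **Reinhard**: each CIELAB channel affinely mapped to reference
  mean/standard deviation; a zero-variance source channel is set flat to
  the reference mean.
* **Macenko**: optical density `OD = −log((I+1)/256)`; pixels with all
  channels below β = 0.15 OD are excluded from estimation; stain vectors
  are the α = 1st/99th-percentile extreme angles in the plane of the top-2
  eigenvectors of the OD covariance (the plane's first axis is oriented
  along the mean OD so the angular distribution does not straddle the
  arctan branch cut); hematoxylin is the vector with the larger red-channel
  absorbance; concentrations are least-squares solved, rescaled to the
  reference 99th percentiles, and the image is rebuilt in the reference
  basis.
* **Grayscale / equalized grayscale**: ITU-R 601 luminance replicated
  across channels, optionally after classic 256-bin histogram
  equalization.
* **HSV augmentation**: light multiplies H, S, V by independent scalars
  from U(0.9, 1.1); heavy multiplies H and S by scalars from U(0.7, 1.3)
  and leaves V untouched. Hue is circular, so hue multiplication wraps
  modulo 1; S and V clip to [0, 1].
* **Stain artifact**: all three HSV channels multiplied by 1+strength with
  strength ≤ 0.05 — a subtle, site-like color shift that survives
  grayscale conversion partially (through the value channel and through
  the differential luminance response of differently-hued structures).

Because the deliverable is source-only, the default normalization
references are derived from a deterministic synthetic reference tile
generated in code at a fixed seed rather than from a shipped image.

## Synthetic cohorts

The generator emulates the *structure* of a multi-site repository, not its
appearance. Tiles are elliptical dark "nuclei" blobs (Poisson count,
Gaussian radii, random orientation and shade) on a pink background with
Gaussian pixel noise. Signals and nuisances:

* **biologic class signal** — a per-class multiplier on blob density
  (default 2× for the "positive-texture" class when enabled);
* **site stain signature** — a per-site multiplicative HSV shift applied
  with the same transform as the stain artifact, at most +5% per channel;
* **slide-level nuisance** — per-slide uniform multipliers on HSV value
  (default half-range 2%), optionally saturation and hue, and on the pixel
  noise SD (default 5%), emulating slide-to-slide staining intensity and
  focus/graininess variation.

Determinism: every random draw comes from a stream keyed by
(seed, entity id) via CRC-32, so identical seeds give byte-identical
cohorts and growing a cohort never perturbs existing slides. A
ground-truth log records every generating parameter (labels, shifts,
jitters, blob counts).

**Confounded scenarios.** `make_confounded_scenario` places its sites on
the corners of the HSV-shift cube {1, 1+0.05·strength}³, shuffled within
corner parity by the seed, and ties the site's latent outcome class to
corner parity. `confounding` interpolates each site's outcome prevalence
between 50/50 (0) and deterministic (1). The corner/parity construction is
deliberate: corners give 5%-per-channel separation, so a flexible model
can memorize each site's signature, while parity is exactly balanced
within every single HSV channel and every channel pair, so no low-order
function of the stain shift predicts the outcome. Under full confounding
the outcome is therefore *memorizable but not generalizable* — the precise
condition under which standard cross-validation inflates accuracy and
preserved-site cross-validation does not. A consequence worth knowing: on
held-out sites the nearest known signatures carry the *opposite* class, so
preserved-site AUROC can fall below 0.5 rather than sitting at it; either
way the model has no true signal, which is what the comparison measures.

## Fold construction

Patients are the optimization unit (slides follow their patient; a
patient's class is the first non-missing value among their slides, and
conflicting values are an error). Missing-outcome patients are excluded
from the count matrix and follow their site into its fold. Continuous
outcomes are quantile-binned (quartiles by default, ties broken by value
then patient id) before optimization.

The preserved-site objective and constraint are given in the README. The
exact solver is a depth-first branch-and-bound over sites pre-sorted by
descending patient count: fold symmetry is broken by allowing a site into
at most one currently-empty fold, infeasible branches (too few sites left
to populate empty folds) are cut, and the lower bound relaxes each class
independently to a water-filling projection (minimize the squared
divergence given the partial fold sums, allowing fractional future
assignments). A short local search provides the incumbent. The 15-site
exactness threshold keeps worst-case enumeration well under a second at
k = 3; beyond it, a seeded greedy-plus-local-search (single-site moves and
pairwise swaps, 1000 restarts by default) is used and the result is
flagged heuristic. Empty folds are never produced — a validation fold with
no sites is meaningless for cross-validation even though the objective
formally permits it. Tie-breaks are deterministic (lexicographic on the
flattened membership matrix in the brute-force oracle).

`standard_folds` is patient-level stratified k-fold ignoring site (per
class, seeded shuffle then round-robin dealing, so fold class proportions
match the cohort within one patient). `site_balanced_folds` spreads each
site evenly over all folds — the splitting scheme for site-prediction
experiments, kept separate from outcome-stratified standard folds.

## Heterogeneity statistics

Categorical outcomes: Pearson chi-squared without continuity correction on
the site-by-class table, df = (rows−1)(cols−1), restricted to sites with
at least 20 slides so small sites do not drive the variance estimates
(threshold configurable); a zero marginal is an error with a
merge-classes recommendation rather than a silent drop. Continuous image
features: one-way ANOVA across the same sites, df_between = sites − 1.
Missing values are dropped per feature (pairwise deletion). Within one
report all p values form a single Benjamini–Hochberg family at
FDR = 0.05; untestable features appear as explicit `skipped` rows.

## Evaluation harness

The baseline tile scorer is a random forest (150 trees, seeded) on the
20-value tile signature, class-balanced by seeded downsampling. A forest
was chosen over a linear model deliberately: like a CNN, it can memorize
arbitrary per-site clusters — including the parity-structured
cluster-label patterns of the confounded scenario, which no linear
function of the features can express — while extrapolating poorly to
unseen clusters. It is a surrogate for, not a re-implementation of, a
deep tile classifier, and reports should label it as such.

Accuracy is one-vs-rest AUROC (rank-based, ties 0.5; macro average over
classes), computed per fold and averaged. Feature prediction aggregates at
slide level (mean tile score per slide, renormalized); the tile-level
false-positive contrast keeps tiles as units and compares
FP/(FP+TP) between fold schemes with a df-1 Pearson chi-squared.
Dispersion comes from 10 slide-level bootstrap resamples per fold — slides
are the independent sampling unit. Fold-level means are the inference
path: paired two-sided t (df = folds−1), pooled two-sample one-sided t
(df = n₁+n₂−2), and one-sample one-sided t against AUROC 0.5
(df = folds−1), matching the conventional df = 2 / 4 / 2 at threefold.
Zero-variance exact ties report p = 1 with a tie flag; zero variance
strictly above the null reports t = +∞, p = 0.

**Experiment drivers.** `run_confounding_experiment` (defaults: 8 sites ×
9 patients × 8 tiles of 64 px, k = 3) trains the scorer under standard and
preserved folds and tests the gap and each arm against chance with BH
correction across the three comparisons. `run_artifact_grid` mirrors a
single-site design — 23 target among 46 background slides — applying the
5% artifact to a fraction of targets and a blob-density signal to another
fraction, with threefold standard CV; every slide passes through the same
color-space processing (a strength-0 artifact pass for unaffected slides)
so nothing but the shift itself differs. The grid's nuisance profile is
stronger than the cohort default (half-ranges: value and saturation 4.5%,
hue 2.5%, noise-SD 25%), chosen so the artifact's grayscale-surviving
footprint is degraded but not erased: grayscale normalization then reduces
detection AUROC below the unnormalized arm without pushing it to chance,
while the hue channel keeps the unnormalized arm near-perfect at full
prevalence.

## Problem sizes and verification

The shipped experiments use 64 px tiles, 6–9 patients per site, and 4–8
tiles per slide, sizes at which the full test suite and the acceptance
script each run in about a minute on one CPU. What passing shows: the
optimizer is exact (50 random instances against exhaustive enumeration),
the feature equations match direct-summation oracles to 1e-10, the tests
are calibrated (type-I error inside the 99% binomial band around 5% over
200 null cohorts), the confounding scenario reproduces the
accuracy-inflation contrast, and the artifact grid reproduces the
monotonicity and partial-grayscale findings. What passing does not show:
anything about real H&E appearance — the texture model has no nuclear
morphology, no JPEG artifacts, no scanner optics; stain variation is a
global multiplicative HSV shift rather than a physical stain-concentration
process; and the forest-on-signatures surrogate is far weaker than a CNN,
so absolute AUROC values do not transfer to real cohorts. The *relative*
phenomena — site memorization under standard CV, its elimination under
preserved-site CV, normalization reducing but not abolishing artifact
detectability — are the claims under test.

## Known limitations

* The heuristic path (> 15 sites) carries no optimality certificate; the
  `optimal` flag distinguishes it.
* Wide contingency tables with empty cells error out rather than merging
  classes automatically.
* Hue wrap-around means a hue multiplier can, for hues near 1, move colors
  discontinuously; the synthetic palette stays away from the wrap point.
* Macenko estimation needs near-pure-stain pixels; tiles without them
  recover vectors with a few degrees of bias, and background tiles raise
  an error by design.
* `PredictionSet` assumes single-label classification with scores summing
  to 1 per tile.
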