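# Methods

## Overview

The package implements a post-segmentation histology analysis: tissue-class
label maps (0 background, 1 epithelium, 2 stroma, 3 fat; single-channel
8-bit PNG with a microns-per-pixel scale) are reduced to a 37-feature
vector per slide, aggregated per patient, and related to percent
fibroglandular volume (FGV) and to invasive-vs-benign diagnosis with
random forests. A synthetic cohort generator with known ground truth makes
every stage testable end to end. This note records the model, the
generator's assumptions, and the numerical choices, so results can be
interpreted and reproduced.

## Feature extraction

**Regions.** Epithelial regions are 8-connected components of label 1.
Components smaller than `min_region_area` (default 50 µm²) are discarded as
segmentation noise; the threshold is in µm² so mixed-resolution cohorts
behave identically. Region area is pixel count × (µm/px)²; the centroid is
the pixel-coordinate mean (0-based, row-major); eccentricity is that of the
ellipse with identical second central moments (0 = circle), as computed by
`skimage.measure.regionprops`.

**Area-Voronoi influence zones.** Every *tissue* pixel (labels 1–3) is
assigned to the region whose pixel set is nearest in Euclidean distance;
a region's own pixels belong to its own zone, and ties go to the lowest
region label. The domain is restricted to the tissue mask rather than the
whole image because glass area is scanner-dependent; with this choice the
zones exactly partition the tissue, which is asserted in tests. The
implementation runs one exact Euclidean distance transform per region and
keeps a running minimum of integer squared distances (strict `<` with
ascending labels implements the tie rule); a brute-force per-pixel scan
with the same tie rule serves as the test oracle.

**Ratios.** `ratio_epi_voronoi = area / voronoi_area ∈ (0, 1]` measures how
completely a region fills its influence zone; `ratio_epi_nonepi =
area / (voronoi_area − area)` is undefined when a region fills its zone
exactly and such values are excluded from summaries.

**Delaunay neighbours.** Region centroids are triangulated
(`scipy.spatial.Delaunay`); the feature is each vertex's degree. Degenerate
inputs fall back to chain adjacency — n = 1 → 0, n = 2 → 1 each, collinear
sets → endpoints 1 and interior 2 after projection on the principal axis —
so small biopsies still yield features instead of errors.

**Summaries and roster.** Each region-level quantity is summarised by mean,
median, population SD (so one region gives SD 0, never a missing cell),
interquartile range (Q3 − Q1, linear-interpolation quantiles) and max. The
canonical roster is 6 global + 11 morphology + 15 Voronoi + 5 Delaunay = 37
features (`histodensity.FEATURE_NAMES`). Slides with no retained region get
zeros for all region-based features plus a `no_epithelium` flag column
(kept out of the 37), so model matrices never contain missing cells.
Patient-level vectors are per-feature medians across the patient's slides.

## Synthetic cohort generator

The generator emulates a biopsy study population in which tissue
composition determines density and epithelial organisation carries the
diagnostic signal.

* **Composition.** Per patient, the fat share of non-epithelial tissue is
  drawn from a Beta distribution with mean `fat/(fat+stroma)` and
  concentration 8 (fat-fraction SD ≈ 0.17, giving a realistically wide FGV
  range); the epithelial fraction is Normal(0.10, 0.03) clipped to
  [0.02, 0.4] and *identically distributed across diagnoses*. Slide-level
  composition jitters around the patient draw (SD 2 percentage points) to
  exercise patient aggregation.
* **Density targets.** `global_fgv = 100 × (1 − fat fraction of tissue)` +
  Normal(0, `fgv_noise_sd`=5) noise, clipped to [0, 100]; `localized_fgv`
  uses a fat share perturbed by SD 0.03 (the peri-lesional neighbourhood
  resembles, but is not identical to, the whole section). Because FGV is
  tied to composition by construction, recovering stroma/fat quantities as
  the top regression features is a falsifiable check, not a tautology.
* **Geometry.** The tissue region is a centred rectangle whose area is
  1 − background. The background fraction varies widely per slide
  (uniform ±0.25 around the configured mean of 0.30, clipped to
  [0.03, 0.7]): biopsy sections fill slides to very different degrees, and
  without this variation absolute (µm²) and normalised (%) quantities would
  be interchangeable and the importance ranking meaningless. Epithelial
  blobs are ellipses with eccentricity Normal(0.6, 0.15); relative sizes
  are lognormal with a floor (min(250 px, half the mean)) so blobs survive
  the min-region-area filter; after painting, blob axes are rescaled (≤ 5
  iterations) until the realised epithelial fraction is within 1% of
  tissue of its target. Fat vs stroma is assigned by thresholding a
  Gaussian random field (σ = 6 px) at the exact quantile, so realised
  class fractions land within ±3 percentage points of their targets.
* **Clustering modes.** `dispersed` places blob centres with a hard core
  (minimum distance 0.6·√(tissue/n), relaxed geometrically on failure);
  `clustered` is a Thomas-style parent–offspring process (n/3 parents,
  offspring SD 0.08 × span); `coalescent` packs ≥ 9 near-equal blobs into
  one dense patch sized so epithelium locally half-fills it, with a mild
  hard core — neighbouring blobs touch and partially merge into large
  irregular regions whose influence zones they nearly fill. This is what
  drives `ratio_epi_voronoi` upward (measured slide means ≈ 0.17 vs ≈ 0.10
  for dispersed at the same epithelial fraction) and is the generator's
  model of invasive growth.
* **Diagnoses and metadata.** Diagnosis counts are quota-based
  (largest-remainder) rather than Bernoulli so tests are deterministic at
  fixed n: `invasive_fraction` (default 0.15) of patients are invasive; the
  remainder split 39/43/8/10% into non-proliferative, proliferative,
  atypia and in-situ, mirroring a diagnostic-biopsy population. Invasive
  patients render with coalescent mode, in-situ with clustered, benign with
  the configured default (dispersed). BMI is drawn inversely related to FGV
  (slope −0.12, noise SD 4); menopausal status is a 58/42 quota. The
  train/test split is 69/31% at patient level. All draws flow from
  `rng_seed` through per-patient/per-slide `SeedSequence` streams, so a
  seed reproduces the cohort byte for byte.

**What the generator does not emulate:** stain appearance, segmentation
errors of the upstream network, pyramidal slide formats, spatial
correlation between composition and diagnosis, biopsy needle geometry, or
any calibration to a real cohort's composition distributions. Passing
tests therefore demonstrate that the pipeline recovers relationships a
cohort genuinely contains — not that real tissue contains them.

## Modelling

Random forests (500 trees, unlimited depth, seeded, single-threaded for
determinism) are used for both tasks, with Gini (impurity) importances
ranked in descending order, ties broken by canonical column order. The
regressor uses `max_features="sqrt"`: the 37 features contain exactly
collinear complements (the three normalised amounts sum to 100), and with
all features available at every split the importance of such a group
collapses onto one arbitrary member; random feature subsetting — the
classifier's default — spreads importance across genuinely informative
features and is the standard remedy. Fitting uses the training split only;
the held-out association is the Spearman rank correlation between
predicted and actual FGV over test patients.

Correlated-feature pruning visits feature pairs in canonical column order
and, when both members of a pair with |Spearman ρ| ≥ 0.85 are still
retained, removes one by a seeded coin flip (|ρ| rather than signed ρ, so
anti-correlated duplicates are also pruned). The cancer analysis drops
in-situ patients, pools benign categories (non-proliferative,
proliferative, atypia) against invasive, stratifies at the
training-population median of the density target (ties to "low"), and
requires both classes in both splits of a stratum, raising
`DegenerateStratumError` otherwise. Patient-level diagnosis, where needed,
is the worst across biopsies. Sensitivity switches (extra covariates such
as BMI, menopausal subgroup filters) are pure supersets/filters with no
bespoke math.

## Evaluation

AUC is the Mann–Whitney concordance probability with ties counted ½
(`sklearn.metrics.roc_auc_score`). Confidence intervals use the
class-stratified percentile bootstrap: patients are resampled with
replacement within each outcome class (so every replicate keeps the
case/control counts and the AUC is always defined), the AUC is recomputed
per replicate (vectorised midrank computation), and the interval is read
from percentiles of the replicate distribution. Default 2000 replicates;
percentile rather than BCa, and the replicate vector is kept on the report
so the endpoints are exactly auditable. Two AUCs from different patients
are compared with the unpaired bootstrap scheme: per replicate both
datasets are resampled class-stratified and the AUC difference recorded;
the statistic is `D = (AUC_a − AUC_b) / SD(bootstrap differences)` with a
two-sided standard-normal p-value. Monte-Carlo checks in the test suite
confirm ~95% CI coverage and ~5% type-I error on binormal scores with
population AUC 0.80 at n = 150/150.

## Problem sizes

Defaults were chosen as the package's study conditions: 580 patients ×
2 slides of 256 × 256 px at 0.5 µm/px (400 train / 180 test), FGV noise
SD 5, invasive fraction 0.15. Calibration checks use 500 Monte-Carlo
datasets with 500 bootstrap replicates each; the permutation check uses 20
repetitions of 200-patient subsamples with 200-tree forests. Smaller
cohorts (40–160 patients, 128 px at 1 µm/px) are used where only
structural behaviour is asserted.

## Known limitations

* The 37-feature roster fixes the {mean, median, SD, IQR, max} summary
  family; a study could plausibly have used a slightly different set, so
  the roster is centralised (`FEATURE_NAMES`) for substitution.
* Influence zones are computed per region with one distance transform
  each; maps with very many regions (≫10²) would benefit from a
  single-pass labelled propagation.
* Regions touching the image border are not treated specially; their
  influence zones simply end at the tissue boundary.
* The AUC comparison assumes independent patient sets; paired designs
  (same patients under two scores) are out of scope.
* With strong class separation the percentile CI degenerates to [1, 1];
  no continuity correction is applied.
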