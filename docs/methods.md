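# Methods

This note documents the models, the defaults and the numerical choices in
`histotype`, and what the synthetic generators do and do not emulate.

## Protein-based subtyping

Input is a long table of H-scores (0–300, staining intensity × percent
positive cells) for six markers — luminal panel CK20, FOXA1, GATA3; basal
panel CD44, CK5, CK14 — scored on up to four 1 mm tissue-microarray cores
per patient (two from the tumor center, two from the invasion front, in
the standard design). Per patient and marker we take the **median over the
available cores**; a patient with no core at all for some marker is a hard
error rather than an imputation, since a missing marker changes the
geometry of the clustering space. Columns are standardized to z-scores
with the sample SD (ddof = 1); a zero-variance marker column is an error
because the subtype axes are then undefined.

Clustering is **Ward linkage on Euclidean distance** (scipy), tree cut at
`k` clusters (`k ∈ {2, 3}`). Linkage and distance are a design choice of
this package: Ward favors compact, roughly spherical clusters, which
matches the block structure such marker tables show; both are recorded in
the output metadata so downstream users can audit them. Cluster naming is
a deterministic centroid rule — luminal maximizes (mean luminal z − mean
basal z), basal the reverse, the remainder is indifferent; ties go to the
lower cluster index and a tie between the two rules aborts with a request
for manual review (it can only occur for pathological, symmetric inputs).
Label assignment is invariant to patient order for generic data because
the merge tree does not depend on input order (exact distance ties are the
only exception).

`k = 3` is the discovery setting; for training the slide classifier the
cohort is restricted to the two most distinctive subtypes (luminal,
basal), since the indifferent group is defined by *absence* of expression
and has no distinctive morphology to learn.

## Slide preprocessing

Tiles are 512 × 512 px, non-overlapping, on a grid **anchored at the slide
origin** so re-annotation never shifts tile identities; a tile is retained
iff area(tile ∩ annotation)/tile-area ≥ 0.5 (inclusive, computed
geometrically with shapely). Coordinates are 0-based, half-open boxes at
level-0 resolution; no magnification harmonization is attempted (left
configurable upstream of this package).

Quality control is a pure function of the pixels with two rules: a pixel
is background iff HSV saturation < 0.08 and value > 220/255; the tile is
rejected as `background` if more than 50 % of pixels are background, and
as `blur` if the variance of the Laplacian of the 0–255 grayscale image is
below 15. These thresholds are package defaults, exposed in the API and
the YAML config; they were chosen to reject white margins and strongly
defocused regions of the synthetic fixtures while accepting both texture
classes with a wide margin.

Stain normalization is Macenko estimation: OD = −log10((I+1)/256); pixels
with OD norm ≤ 0.15 are discarded as non-tissue (≥ 100 tissue pixels
required); the stain plane is the span of the top-2 right singular vectors
of the tissue OD cloud; the two stain vectors are the 1st and 99th angle
percentiles of the projected cloud; hematoxylin is the vector with the
larger blue-channel OD. Concentrations are least-squares solved and
clipped at zero (a fast non-negative projection — adequate here because
the synthetic tiles are true two-stain mixtures with tiny residuals), and
the per-stain 99th percentile defines the concentration scale.
Normalization maps concentrations to a fixed reference profile: the
canonical H&E OD vectors H = (0.65, 0.70, 0.29), E = (0.07, 0.99, 0.11)
(unit-normalized) with reference concentrations (1.9705, 1.0308). Tiles
with too little tissue to estimate a profile pass through unchanged rather
than erroring inside a batch.

## Cross-validation and training

Splitting is **plain random at patient level** — every repetition draws
its own seeded permutation of the patient list and cuts it into near-equal
folds (earlier folds take the remainder). Stratified assignment is
available but off by default; if a training fold ends up class-empty,
balancing raises and the user re-seeds or stratifies. Class balance is
enforced by downsampling every class to the minority tile count, without
replacement, seeded, leaving validation untouched. Plans and balanced sets
are bit-identical for identical inputs and seeds.

The tile classifier is an sklearn-style estimator over a pluggable
backbone. The default `tiny` backbone block-averages tiles to 64 px,
flattens, and trains a one-hidden-layer (64 units, tanh) softmax network
with seeded mini-batch SGD (momentum 0.9, learning rate 0.05, batch 32,
6–8 epochs in the standard configurations). It is single-threaded NumPy,
hence exactly reproducible; with zero epochs it sits at its near-symmetric
random initialization and predicts ≈ 0.5. A `resnet50` registry entry
(ImageNet transfer learning at 224 px input) is available for
installations providing torch/torchvision; arbitrary backbones can be
plugged in via `register_backbone`. Optional augmentation is restricted to
90° rotations and flips (histology has no canonical orientation), off by
default.

## Slide-level inference

p<sup>WSI</sup> is the arithmetic mean of tile probabilities per class;
the call is the argmax. Confidence bands partition [0.5, 1]: **high** iff
max p<sup>WSI</sup> ≥ 0.7, **low** iff ≤ 0.6, **intermediate** in the open
gap (0.6, 0.7) — the gap band is named and reported rather than silently
dropped. Band boundaries are compared with a 1e-9 absolute tolerance so
that means that equal a boundary in exact arithmetic (e.g. mean of 0.55
and 0.65) band by the exact rule rather than by floating-point rounding.
An exact 0.5/0.5 tie is defined, not left to chance: labeled luminal,
banded low, and flagged. Ensembling over the three fold models of a
repetition averages their slide-level predictions and takes the argmax;
any other model count must be explicitly allowed.

Prediction maps hold, per retained tile, the winning class and its
probability; the rendered overlay colors luminal red and basal blue with
alpha = (p − 0.5)·2. Heterogeneity screening assigns tiles with winning
probability ≥ 0.6 to their class, computes 4-connected components per
class on the tile grid, and flags the slide as a candidate iff **both**
classes own a component covering ≥ 20 % of the retained tiles. The rule
and both parameters are this package's operationalization of what is
otherwise a visual judgement; they are fully exposed.

## Metrics and tests

AUROC uses basal as the positive class (as do precision/recall/F1;
macro-averaged variants are available by flag) and equals the
Mann–Whitney pair statistic; fold metrics are summarized as mean ±
t(0.975, K−1)·SD/√K — for K = 3 the multiplier is ≈ 4.30265. Confusion
matrices concatenate the validation folds of one repetition; a slide
predicted twice is a split-leakage error. Fisher's exact test, the
Wilcoxon rank-sum, Kruskal–Wallis, and one-tailed Wilcoxon signed-rank
tests (zeros dropped) use exact enumeration up to n = 25 and the
tie-corrected normal approximation above; all are delegated to scipy and
cross-checked in the test suite against independent brute-force oracles
(pair counting, log-factorial hypergeometric enumeration, flood fill,
per-pixel rasterization). Note the exact Fisher test is conservative at
small n: under planted independence at n = 24 its empirical type-I rate
sits near 2–3 %, not at the nominal 5 %.

## Synthetic generators

The H-score generator plants three subtypes: expressed markers ~
N(220, 40²), silenced ~ N(20, 15²), indifferent ~ N(15, 10²) on both
panels; per patient a latent marker mean is drawn and four cores add
N(0, 15²) noise; everything truncates to [0, 300]. These effect sizes
give a clearly separated but noisy block structure; Ward clustering
recovers planted labels essentially perfectly, so recovery failures in
a user's data indicate weaker separation than this reference condition.

Pseudo-slides (default 3072 × 2048 px) are rendered through the canonical
H&E stain matrix from two concentration fields: the luminal texture is a
dense Poisson field of dark hematoxylin ellipses (radius 4–8 px, density
4.5·10⁻³ px⁻²) on pink stroma; the basal texture is oriented eosin fibers
with sparse bright keratin blobs and few nuclei. The density default was
chosen so the mean blue-channel OD of luminal tiles exceeds basal tiles by
≥ 0.1, making the two classes separable even from mean color — by design:
the end-to-end experiment then tests the *pipeline mechanics* (splitting,
balancing, aggregation, banding), not a hard representation-learning
problem. Consequently a perfect synthetic AUROC says nothing about
real-cohort difficulty, where morphology is subtle, labels are weak and
scanners vary. Slides carry a full-rectangle tumor annotation, optional
white-margin and Gaussian-blur artifacts for QC tests, a global (H, E)
concentration scale as a crude scanner model, and a per-tile ground-truth
grid; heterogeneous slides split the tumor into two contiguous blocks at a
tile-aligned boundary by default. Per-slide seeds are hashed from (master
seed, slide index), so cohorts are stable under count changes; metadata
columns (tumor type, PD-L1, FGFR3) are planted with a configurable
association strength a — P(concordant level) = 0.5 + a/2.

## Problem sizes

The standard synthetic experiment uses 12 + 12 slides (24 tiles each,
576 tiles), 3-fold single-repetition cross-validation and the tiny
backbone at 64 px — about three minutes on one CPU; statistical suites use
1000 AUROC instances, 200 Fisher tables, 200 independence replicates, 20
clustering seeds. These sizes were chosen to make the full suite a
routine local run while keeping every estimate's Monte-Carlo error small
relative to its acceptance margin.

## Known limitations

- No multi-resolution handling; slides are consumed at level 0 and
  micron-per-pixel harmonization is out of scope.
- No automatic tumor segmentation; annotations are required.
- The default backbone is deliberately small; real-cohort performance
  claims require a pretrained CNN backbone and real slides.
- Heterogeneity detection is a screening rule on the prediction map, not
  a spatial-statistics model.
- No consensus clustering or bootstrap stability for the subtyper, and no
  survival analysis.
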