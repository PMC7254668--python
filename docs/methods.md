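# Methods

`deltarad` implements a delta-radiomics pipeline for classifying breast
cancer pathologic complete response (pCR) to neoadjuvant chemotherapy
(NAC) from paired pre-/post-treatment dynamic contrast-enhanced (DCE)
MRI.  Each exam is a co-registered stack of one pre-contrast and three
post-contrast T1-weighted fat-suppressed volumes.  The chain is:
segmentation from a single-slice seed → histogram standardization →
255-entry feature vector → MRMR → elastic net → SMOTE → recursive-feature-
elimination random forest (RFE-RF) → ROC evaluation.

## Synthetic phantom cohort

No patient data ship with the package; every stage is exercised on a
generator of paired-exam phantoms.

A lesion is a sphere (radius drawn uniformly from 4–8 mm) on a weakly
textured background at 100 intensity units.  Lesion voxels follow a
wash-in/plateau enhancement curve with per-phase multipliers
(1, 2.2, 2.6, 2.4) — pre-contrast is the reference, and the background
does not enhance (fat suppression).  A smooth multiplicative texture
field (low-pass-filtered Gaussian noise, relative amplitude 0.15 inside
the lesion, 0.05 outside) keeps co-occurrence statistics non-degenerate:
a constant lesion would have zero GLCM entropy and hide texture bugs.
Additive Gaussian noise (sd 5, i.e. 5% of background; a Rician option
exists) and a per-exam global gain jitter of ±15% emulate scan noise and
inter-scan intensity scale drift.

Complete responders shrink after treatment: the post-NAC radius and the
enhancement above baseline are both reduced by `responder_shrinkage`
(default 0.7), floored at a faint residual "tumor bed" of radius 2.5 mm
enhancing at 15% of the original amplitude, so post-treatment
segmentation of responders stays well posed.  Non-responders re-present
the lesion at full size with a fresh noise realization.  Default cohort
proportions mirror a realistic NAC population: 74/278 ≈ 27% pCR, and
molecular subtypes sampled at (34.2, 23.4, 16.2, 26.2)% for
(HR+HER2−, HR+HER2+, HR−HER2+, TN).

What the phantom does **not** model: breast anatomy, pharmacokinetic
(Tofts) enhancement, B1/bias fields, inter-exam misregistration, and any
association between molecular subtype and response.  Passing tests
therefore demonstrate that the machinery is correct and leakage-free on
a separable cohort — not that the published patient-level accuracy
transfers to real data (the phantom's treatment effect is deliberately
strong, so end-to-end AUROCs near 1 are expected rather than the 0.7–0.85
range seen clinically).

## Segmentation

A radiologist-style seed is emulated by eroding the central axial slice
of the truth mask by one voxel (a "conservative" single-slice outline).
Per voxel the exam is summarized by an 8-vector: the four phase
intensities, the three temporal differences (post-contrast k minus
pre-contrast), and the trace statistic — for intensities
(I₀, I₁, I₂, I₃) build the symmetric 4×4 matrix with Mᵢᵢ = Iᵢ² and
Mᵢⱼ = (Iᵢ − Iⱼ)², and take the sum of its three largest eigenvalues.
Features are standardized by the ROI mean/sd before model fitting so the
quartic-scale trace channel does not dominate.

Two-component full-covariance Gaussian mixtures model foreground (seed
voxels) and background.  The background band is a 3-voxel shell around
the seed bounding box *expanded axially to the lesion's expected extent*
(taken from the in-plane half-extent, lesions being roughly isotropic);
a shell directly around the one-slice-thick seed box would sit inside
the tumor above and below the seed slice.

Growth is a cellular automaton on the 26-neighborhood: each voxel holds
a label and a strength in [0, 1]; a neighbor q attacks p with strength
θ_q · P(label_q | x_p), posteriors coming from the two mixtures with
equal priors.  Seeds (foreground) and the background band start at
strength 1 and are never overturned.  Iteration stops when fewer than
0.1% of labels change or after 200 sweeps; the output is the foreground
component connected to the seed, and one mask serves all four phases of
the exam.  A warning is raised if the mask reaches most volume faces
(likely leak).  On noiseless sphere phantoms the result matches ground
truth to within the one-voxel boundary band; at noise equal to 10% of
the first-post-contrast enhancement, Dice stays above 0.95.

## Histogram standardization

Landmark (percentile-matching) standardization: decile landmarks between
the 1st and 99th percentile, a standard scale of [0, 4095], and
foreground defined by Otsu thresholding of the pre-contrast phase.  The
standard scale is the across-volume mean of each volume's landmarks
mapped affinely onto the range; application is the monotone
piecewise-linear map sending a volume's own landmarks onto the standard
ones, clamped at the range ends.  Maps are learned per phase position
(pre, post1, post2, post3) on **training exams only** and then applied
to all exams, so the intensity scale never sees test data.  Because the
transform is built from a volume's own percentiles, a volume and any
globally rescaled copy map to identical outputs — intensity features
become scale-invariant.

## Feature scheme (255 entries)

Per phase volume, within the tumor mask (21 features):

* first order (4): mean, sd (sample, ddof = 1), excess kurtosis,
  skewness; skewness/kurtosis are defined as 0 for constant regions.
* Haralick (5) from a pooled 3-D gray-level co-occurrence matrix:
  energy Σp², entropy −Σp log₂p, correlation (0 when a marginal variance
  vanishes), contrast Σ(i−j)²p, homogeneity Σp/(1+|i−j|).  The GLCM uses
  32 gray levels (min–max quantization within the mask), the 13 unique
  distance-1 directions accumulated symmetrically into a single pooled
  matrix, pairs restricted to voxels inside the mask.
* Gabor edge summaries (2): mean response magnitude within the mask at
  θ = 0° and 90°, bandwidth 1.414, computed slice-wise in the axial
  plane with reflect padding.  The filter wavelength is 4 voxels
  (frequency 0.25/voxel, σ from the standard bandwidth–sigma relation);
  the real kernel is re-centered to zero DC so constant regions give
  zero edge response.
* Haralick on the two Gabor magnitude maps (10).

One intra-tumor cluster entropy per exam completes the 85: per-voxel
local Haralick features (5 textures over a 3³ sliding window at 8 gray
levels, computed on the first post-contrast volume) are clustered with
self-tuning spectral clustering — affinity exp(−d²/σᵢσⱼ) with σᵢ the
distance to the 7th nearest neighbor at positive distance (coincident
feature rows carry no scale information), cluster count K ∈ [1, 6] by
the largest eigengap of the normalized Laplacian, k-means on the
row-normalized spectral embedding — and the statistic is the Shannon
entropy of the cluster-size proportions.  For tractability at cohort
scale a seed-controlled subsample of at most 250 voxels is clustered.
Masks smaller than the 27-voxel window are assigned entropy 0 (no
sub-regional heterogeneity is resolvable).  This entropy-of-proportions
reading of "textural variability within sub-regions" is an
interpretation; users comparing against other cluster-entropy
implementations should check the convention.

Deltas are `diff_x = af_x − bef_x` for all 85 per-exam features:
85 + 85 + 85 = 255, named `{bef|af|diff}_{pre|post1|post2|post3}_{feature}`
plus `{timing}_clusterentropy`.  The "MRI intensity features" excluded
from model variant 3 are the 12 mean-intensity entries
(bef/af/diff × 4 phases), leaving 243.

## Selection and classification

All rows are lesions; the cohort is split 80/20 stratified by response
(training count = ⌊0.8 n⌋ with per-class largest-remainder allocation:
278 → 222/56).  Inside every training fit, in order:

1. **z-scoring** by training mean/sd (zero-variance features dropped).
2. **MRMR** (mutual-information difference criterion) on tertile-binned
   features; top 80% kept (255 → 204).  For variant 3 the same rule
   gives 243 → 194.
3. **Elastic-net logistic regression**, penalty and mixing parameter
   (grid 0.1/0.5/0.9) chosen by 3-fold cross-validated log-loss;
   features with |standardized coefficient| > 0.1 are kept.  An empty
   selection falls back to the MRMR subset.
4. **SMOTE**: each synthetic draw picks the minority class with
   probability 3/4 (the 3:1 minority weighting), a random member of the
   class, and a point uniformly on the segment to one of its K = 5
   nearest same-class neighbors; draws stop when the classes balance.
   Only training rows are ever augmented.  For variant 2 the one-hot
   subtype indicators pass through SMOTE and may be fractional in
   synthetic rows — the forest is insensitive to this.
5. **RFE-RF** with repeated (3×), nested five-fold cross-validation:
   steps 1–4 are refit inside every outer training fold; a ranking
   forest orders features by Gini importance and each candidate subset
   size from the dyadic grid {2, 4, 8, 16, 32, 64, all} is scored on the
   held-out fold.  Scores are pooled per size by nominal grid label
   (fold-wise feature counts differ).  The *inner* selection of each
   fold's subset size uses the forests' out-of-bag AUC on that fold's
   training rows, so the headline cross-validation AUC — the average of
   per-fold held-out AUCs at the inner-chosen sizes — never shares data
   with the size decision.  (Reporting instead the maximum of the pooled
   per-size AUCs would inflate a label-permuted null cohort's CV AUC a
   few points above chance.)  Fold AUCs are averaged, not pooled,
   because folds evaluated at different sizes have incomparable score
   calibrations.  The final 1000-tree forest is refit on the full
   training set at the size with the best overall mean out-of-fold AUC
   (ties to the smaller subset).
   The forests used inside the size search default to 150 trees — the
   AUC ranking of subset sizes is insensitive to tree count well before
   1000 — while the deliverable classifier always uses 1000.

Variants: 1 = 255 radiomics features; 2 = variant 1 plus one-hot
molecular subtype appended **after** the radiomics pre-selection;
3 = the 243 non-intensity features.

The operating threshold is the Youden point of the pooled out-of-fold
scores and is frozen before the test set is touched.  Selection,
scaling, SMOTE and threshold are all functions of training rows only;
the tests verify that perturbing test rows leaves the trained model
bit-identical.

## Evaluation

AUROC is the tie-corrected Mann–Whitney statistic; its confidence
interval and the paired two-curve comparison use the DeLong
placement-value variance (identical score vectors are reported as
p = 1).  Sensitivity/specificity/PPV/NPV are computed with **no-pCR as
the positive class** (detecting residual disease) and carry exact
Clopper–Pearson intervals.  Univariate feature–response association uses
the two-sided Wilcoxon rank-sum test with Benjamini–Hochberg correction
across the tested feature family; constant features are assigned p = 1.

## Problem sizes and numerical choices

The shipped configuration runs a 278-lesion cohort of 30³-voxel volumes
(1 mm isotropic): large enough for 4–8 mm lesions plus a background
margin, small enough that the full pipeline (segmentation, extraction,
nested-CV training) completes in minutes on one core.  The
label-permutation null check trains on the whole cohort with two CV
repeats and 150-tree forests: the null distribution of the AUC depends
on sample counts, not forest size; using all 278 rows and averaging
over repeats tightens the chance-level band.  Known numeric edge cases: degenerate
(single-level) masks produce a one-cell GLCM; constant volumes are
rejected by the standardizer; flat histogram stretches get an epsilon to
keep landmarks strictly increasing; mixture components are reduced with
a warning when a seed is very small.

## Known limitations

* The GrowCut strength rule and stopping criterion are reasonable
  defaults; the original in-house algorithm's exact update is not
  published in the sources available here.
* The elastic-net "importance" is read as the absolute standardized
  coefficient, and the published 255 → 204 → 156 counts are
  data-dependent beyond the fixed 80% rule (note that top-80% of 243 is
  194, not the 204 sometimes quoted for the intensity-free variant).
* Cluster entropy's sub-region granularity (window, levels, subsample)
  is an implementation choice; only its qualitative behaviour
  (0 for homogeneous, ~1 bit for two equal texture-distinct blobs,
  ≤ log₂K) is contract-tested.
* Radiologist correction of segmentations, multi-lesion separation and
  pre/post registration are out of scope.
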