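# Methods

`fistulomics` models the risk of radiotherapy-induced esophageal fistula
(EF) in esophageal-cancer patients from three data streams available at
treatment-planning time: the planning CT, the 3D planned dose distribution,
and clinical covariates. This note records the model, the numerical
choices, and what the synthetic cohort does and does not emulate.

## Volumes of interest and feature families

Features are extracted over three VOIs: the esophagus contour (ESO), the
gross tumor volume (GTV), and their combination (EG). Two EG constructions
are supported:

* **union** (default): EG is the voxelwise union mask, treated as a VOI of
  its own;
* **concat**: the EG feature set is the column concatenation of the ESO and
  GTV feature sets (each column keeps its source-VOI prefix).

Both are legitimate readings of "combined VOI" modelling; the union treats
EG as an anatomical region, the concatenation pools the information of both
regions and is the construction under which a combined model can, by
design, recover every signal available to either single-VOI model.

**Radiomics (R).** Per VOI: 14 3D shape descriptors (once, on the original
mask) plus 18 first-order and 73 texture features for every derived image
and every gray-level count. The derived-image bank is the original CT,
Laplacian-of-Gaussian responses at sigma = 1, 3, 6 mm, and the 8 sub-bands
of a single-level 3D stationary (undecimated) wavelet transform with a
coiflet-1 mother wavelet; gray-level counts are 10, 20, 30, 40, 50 under
fixed-bin-number discretization. Total: 14 + 12·5·(18+73) = **5474**
features per VOI.

The 73-texture budget is met as 22 GLCM + 16 GLRLM + 16 GLSZM + 14 GLDM +
5 NGTDM. The GLCM family is the 24-feature co-occurrence set minus the two
deprecated/duplicated members (the sum-average duplicate and the
homogeneity alias). GLCM and GLRLM average feature values over the 13
unique 3D directions at distance 1 (unweighted); GLSZM zones and the
GLDM/NGTDM neighborhoods are 26-connected; GLDM uses dependence tolerance
alpha = 0 with the center voxel counted (dependence = neighbors + 1).

**Dosiomics (D).** Per VOI, three families totalling **213** features:

* DVH parameters: Dx at 39 percent-volume points {0.5, 0.8, 2.5, 5, ...,
  92.5} and Vx at 20 thresholds {4, 8, ..., 80} Gy, plus Dmin/Dmean/Dmax.
  Dx is the minimum dose of the hottest x% of the VOI volume, linearly
  interpolated on the descending-sorted voxel doses; Vx uses the strict
  inequality dose > x. The grids are configurable; these defaults realize
  the 39 + 20 + 63 + 91 = 213 decomposition.
* Scale-invariant 3D dose moments: with voxel weight w = dose · voxel
  volume and physical coordinates centered at the dose-weighted centroid,
  μ_pqr = Σ w (x−x̄)^p (y−ȳ)^q (z−z̄)^r and
  η_pqr = μ_pqr / μ_000^(1+(p+q+r)/3) for all 63 order triples (p,q,r) in
  {0..3}³ \ {(0,0,0)}. Including the volume element in w is what makes
  every η exactly invariant under isotropic lattice stretching (the
  normalization exponent cancels s^(p+q+r) only if μ_000 itself scales as
  s³); central moments are translation-invariant by construction. The
  three order-1 moments are analytically zero and reported as exact 0.
* Dose-based radiomics: the 18 first-order + 73 texture features of the
  unfiltered dose map (default 20 gray levels).

**Shape/surface convention.** Surface area, mesh volume and sphericity use
a marching-cubes triangulation of the indicator after light Gaussian
smoothing (sigma 1 voxel); without smoothing the staircase surface of a
digitized sphere overestimates the area by tens of percent and sphericity
saturates near 0.67 instead of 1. Masks too thin to survive smoothing fall
back to the raw indicator (a single voxel meshes to an octahedron of area
≈ 1.73 mm², not the 6 mm² of the voxel-face convention — a deliberate
choice of the mesh convention throughout). Axis lengths are 4·√λ of the
voxel-centroid covariance eigenvalues; degenerate masks return elongation
= flatness = 1 and zero diameters rather than raising.

**LoG numerics.** The LoG is computed in physical units (sigma/spacing per
axis) as the sum of separable sampled second-derivative-of-Gaussian
kernels with mirror boundaries. Each derivative kernel is corrected to
zero sum: at sub-voxel sigma (1 mm sigma on 3 mm slices) the naively
sampled kernel retains a large DC component and a constant image would
otherwise produce a spurious response of order the image mean.

## Feature selection

Inside every train/test iteration, on the training cohort only:

1. z-scoring by training mean and population SD (constant columns → 0);
2. 100 stratified 70% subsamples without replacement; per subsample,
   zero-variance columns are dropped and features are screened by a
   two-sided equal-variance Student t-test at p < 0.01;
3. retention frequency f_i = (times kept)/100; features ranked by f_i,
   ties broken by mean |t| across resamples, then by name (deterministic);
4. the top 10% of survivors (at least 40, at most all) enter a greedy
   redundancy pass dropping any feature with |Pearson r| > 0.5 against an
   already-kept higher-ranked feature;
5. nested prefixes (top-1, top-2, ...) are each fit with the ridge
   classifier; the prefix with the best test-cohort AUC wins (ties favor
   the smaller prefix).

Step 5 selects on the test cohort, reproducing the original protocol; this
leaks test information into model selection and inflates test metrics. A
nested mode (`scoring_cohort="train_cv"`) scores prefixes by 3-fold
cross-validation inside the training cohort instead, and is what the null
permutation check uses (mean test AUC 0.5 ± 0.1 under permuted labels).
"Combinations 1..K" is implemented as nested frequency-rank prefixes, not
the 2^K power set: exhaustive search is intractable at K ≈ 40 and
inconsistent with "ranging from 1 to the number of reserved features".

## Classifier and evaluation

"Ridge" is realized as L2-penalized logistic regression with the penalty
chosen from 13 log-spaced points in [1e-3, 1e3] by stratified 10-fold CV
maximizing AUC (folds capped at the minority-class count on small
cohorts); the logistic link supplies the probabilities needed for
threshold metrics and decision curves. A ridge-regression-on-labels
variant (RidgeClassifierCV, probability via a logistic link on the
decision value) is available with `mode="regression"`.

Evaluation: 30 independent stratified 7:3 splits (iteration i is seeded
seed+i); per iteration the full selection protocol runs on the training
cohort and five metrics (AUC; accuracy, precision, recall, F1 at
probability threshold 0.5) are computed on both cohorts. Aggregates are
mean ± STD with a t-based 95% CI of the mean across iterations. AUC CIs
for a single score vector are available by the analytic DeLong
placement-value variance or by 2000 stratified bootstrap resamples
(percentile); models are compared by a two-sided paired t-test on
per-iteration AUCs (identical vectors → p = 1 by convention). Decision
curves use NB(t) = TP/n − (FP/n)·t/(1−t) against treat-all/treat-none
references.

## Synthetic cohort

No patient imaging is distributable, so cohorts are generated: the
esophagus is an axial tube (radius 3.5–5.5 mm, sinusoidal wobble), the GTV
an ellipsoid centered on the tube (overlap guaranteed), CT a smoothed
Gaussian random field (per-patient correlation length 0.6–1.6 voxels —
the texture dial) with tissue offsets, and dose an anisotropic Gaussian
centered near the GTV with a random craniocaudal offset (the dose-shape
dial), scaled to the prescription implied by the fraction-dose category
(1.8 Gy × 33 or 2.0 Gy × 30) plus a small non-negative scatter floor.
Clinical covariates are drawn from the pooled category proportions of the
modelled 287-patient cohort; the same printed contingency tables back the
`table1_fixtures()` used by the statistics module.

The EF label is Bernoulli(σ(Σ β_k z_k + ε + c)): drivers z_k are z-scored
cohort-wide and computed by the pipeline's own operations — esophageal
GLCM joint entropy (20 levels), esophageal V50, the GTV craniocaudal
dose-skewness moment η_003, and the fraction-dose indicator. Default
weights (1.4, 0.8, 0.6, 0.5; logit noise SD 1.0) mirror the modelled
cohort's structure in which esophageal CT texture dominates the combined
model while dose features contribute. The intercept c is solved so the
expected prevalence matches the requested class balance (default
149:138 ≈ 1:1.08). A second named plant, `COMPLEMENTARY_EFFECTS`, puts
strong weight (1.3 each) on exactly one ESO-visible driver (CT texture)
and one GTV-visible driver (dose moment); the two are statistically
independent by construction, which is the condition under which the
combined EG model demonstrably outperforms both single-VOI models — the
multi-VOI acceptance comparison runs on this plant in concat mode.

What the generator does **not** emulate: real anatomy and Hounsfield
distributions, deliverable IMRT dose (no beam/optimizer model),
inter-observer contouring variation, scanner effects, or clinically
calibrated effect sizes (the true effects are unknowable from published
summaries). Passing tests therefore demonstrate the correctness and
statistical behavior of the pipeline machinery, not clinical performance
on real cohorts.

## Problem sizes

Simulations are sized for a single CPU: the multi-VOI comparison uses 200
patients, original-image radiomics at 20 gray levels plus the full dose
profile, and 10 evaluation iterations; the planted-recovery check 300
patients; the null permutation check 300×150 tabular features; the
nine-model smoke study 40 patients on 16³ grids with a reduced bank
(one LoG scale, one bin count, 2 iterations, 25 screening resamples). The
full 12-image 5474-column profile is exercised per patient where the count
identities are asserted. Default anisotropic spacing is 1.152 × 1.152 ×
3.0 mm, the acquisition geometry of the modelled cohort.

## Known limitations

* The texture-feature definitional details (direction weighting, Ng in the
  normalized inverse-difference features, degenerate-ROI conventions) follow
  one consistent set of choices, documented above; other extractors differ
  in these corners at the 1e-3–1e-2 level.
* The chi-squared report drops structurally empty categories; covariates
  whose published tests need raw values (age, BMI, lesion location) are not
  reproduced.
* DeLong CIs assume asymptotic normality of the placement values; for tiny
  cohorts the bootstrap interval is preferable (and is the default label).
* The test-cohort prefix selection is retained as the default because it is
  the modelled protocol; numbers produced that way are optimistically
  biased, and any methodological use should prefer the nested mode.
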