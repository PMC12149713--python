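# Methods

`habitatpipe` implements an IVIM-based habitat-imaging analysis for
predicting pathologic complete response (pCR) to neoadjuvant chemotherapy
from multi-b-value diffusion MRI, together with a synthetic digital-phantom
cohort generator that makes every stage testable without patient data.

## The IVIM model

Each voxel's diffusion-weighted signal is modeled as a two-compartment
biexponential,

    S(b) = S0 [ f exp(-b D*) + (1 - f) exp(-b D) ],

where `D` (mm²/s) is the pure tissue diffusion coefficient, `D*` (mm²/s) the
pseudo-diffusion coefficient of capillary microcirculation, and `f` the
perfusion fraction.  The acquisition scheme is the nine-b-value protocol
b = 0, 30, 50, 80, 120, 160, 200, 500, 1000 s/mm² with per-b signal averages
(1, 2, 2, 2, 2, 2, 2, 2, 3).

**Estimation.**  Fitting is segmented-initialized nonlinear least squares:

1. a log-linear fit on the high-b tail (b ≥ `b_split`, default 200 s/mm²,
   the natural gap in the scheme) gives `D` and the tissue intercept;
2. the intercept deficit relative to S(0) gives `f`;
3. a bounded one-dimensional search gives `D*`;
4. all four parameters are refined by bounded trust-region least squares on
   all b-values (analytic Jacobian, tolerances 1e-10).

**Bounds.**  D ∈ [1e-6, 3e-3], D* ∈ [6e-3, 0.3], f ∈ [0, 0.5], S0 > 0.
The D* floor sits a factor two above the D ceiling deliberately: with a
merely touching gap, noisy voxels with high tissue diffusivity (necrotic
tissue, D ≈ 2e-3) are frequently fit by a swapped mode — `f` pinned at its
upper bound and `D*` at its floor imitating fast monoexponential decay —
which corrupted roughly a fifth of high-D voxels at SNR 50 in phantom
studies and capped habitat recovery at ARI ≈ 0.82.  The factor-two gap
restores identifiability (ARI ≈ 0.99 on the same phantom) at the cost of
excluding the rarely resolvable D* band below 6e-3 mm²/s.  All bounds are
configurable per fit.  The D floor of 1e-6 (rather than a larger value)
keeps a perfectly flat decay representable as D → 0.

Degenerate voxels (non-finite signal, S(0) ≤ 0) are flagged and filled with
NaN, never raised, so whole-volume fitting is robust; downstream stages skip
unconverged voxels.

## Digital phantoms and cohorts

A phantom is an ellipsoidal "tumor" whose voxels belong to 2–4 habitats with
distinct (S0, D, f, D*).  Two geometries are provided: `nested_shells`
(concentric ellipsoid shells, deterministic and fraction-exact through
largest-remainder rounding — every habitat's voxel count is within one voxel
of its target share) and `random_blobs` (thresholded smooth Gaussian random
field, more organic shapes with the same fraction-exact quantile split).

Signals are the exact forward model plus Rician noise
sqrt((S + n1)² + n2²), n1, n2 ~ N(0, σ²), applied independently per
b-value image with σ scaled by 1/sqrt(n_averages).  The default σ = 2 at
S0 = 100 gives SNR 50 at b = 0, a deliberately clinical-ish level at which
fits are stable but visibly noisy.

**Default habitat archetypes** follow the physiology of the habitat map:
label 1 high perfusion (f = 0.22), label 2 high cellularity (low f, low D),
label 3 necrotic-like (low f, high D).  No quantitative per-habitat values
are published for this application, so the defaults are standard breast
IVIM magnitudes (D ≈ 0.7–1.6e-3, f ≈ 0.05–0.22, D* ≈ 12–30e-3 mm²/s) and
are fully config-exposed.  A `well_separated_habitats` preset widens the
(f, D) separations for stability studies where cluster recovery should be
essentially exact.

**Cohorts.**  Per patient, habitat volume fractions are jittered on the log
scale (sd 0.45, renormalized) and IVIM parameters multiplicatively (relative
sd 0.05).  The binary outcome is Bernoulli with
P(pCR) = expit(intercept + Σ c_k · fraction_k): response is favoured by the
perfused and cellular habitats and disfavoured by the necrotic one.  The
default coefficients (7, 3.5, −7) with intercept −1.7 give ≈ 36% prevalence
(matching the emulated cohort) and an oracle discriminability of the
generating linear predictor of ≈ 0.81 AUC; the `strong_effect_cohort`
preset (12, 6, −12; intercept −2.75) gives ≈ 0.90 oracle AUC at the same
prevalence.  These oracle levels were fixed from generator-level simulation
of the outcome model alone, before any pipeline was run, and are the study
conditions for the end-to-end checks.  Train/test membership is a seeded
shuffle (default 30% test).

What the phantoms do **not** emulate: anatomy, coil or field inhomogeneity,
motion, partial-volume mixtures at habitat boundaries, spatial noise
correlation, or any texture beyond the habitat partition itself.  Passing
tests therefore demonstrate algorithmic correctness and statistical sanity
of the pipeline, not clinical performance on real breast MRI.

## Habitat segmentation

Voxels of the training patients are pooled, z-scored with training-voxel
statistics, and clustered with K-means (k-means++, 10 restarts, tol 1e-6,
max 300 iterations).  Clustering is population-level: centroids fit once on
the training pool are applied to every patient, so "habitat 2" means the
same thing in every case.  Rows are canonically sorted before fitting, which
makes the fitted centroids invariant to voxel order.  Channels default to
(f, D) with K = 3 — the combination reported to perform best in the emulated
study — with D* excluded by default as the noisiest parameter; channels and
K are configurable.

Labels are permuted into a fixed physiological order: label 1 is the
cluster with the highest raw-f centroid (high perfusion), remaining labels
ascend in raw D (label 2 low-f/low-D cellular, label 3 low-f/high-D
necrotic).  Assignment is nearest centroid in the normalized space; exact
ties go to the smallest label.

**Choosing K.**  The published procedure is only named ("a bootstrap
approach"), so the implementation here is an explicit reconstruction:
for each candidate K, cluster the full pool, then recluster B bootstrap
resamples and score the adjusted Rand index between each resample's
partition and the full-data labels on the resampled voxels; the K with the
highest mean ARI wins, preferring smaller K on ties.  This is the standard
prediction-strength/stability family of criteria; it is documented as a
reconstruction, not as the original study's verbatim method.

## Features

For each habitat (and optionally the whole tumor) and each map channel the
18 first-order statistics are computed: mean, median, minimum, maximum,
range, 10th/90th percentile, interquartile range, variance, skewness,
kurtosis (Pearson, excess + 3), energy, total energy (energy × voxel
volume), RMS, mean absolute deviation, robust MAD (within [P10, P90]),
entropy and uniformity.  Entropy/uniformity use a fixed 64-bin histogram
over the region's own range (the source feature list and discretization are
not published; this is the standard first-order family with its usual
defaults, config-exposed).  Percentiles interpolate linearly between order
statistics.  Skewness/kurtosis of constant regions are defined as 0 so a
degenerate habitat does not drop the case.  Each region also contributes
its volume (voxel count × voxel volume) and volume ratio; ratios across
habitats sum to 1 per case.

A habitat empty for some case yields missing values and a flag — zeros
would fabricate signal.  Downstream, columns with > 20% missing are dropped
and the rest imputed with the training median.

## Feature selection

The staged chain, fit on training rows only:

1. **ICC filter** (when a second segmentation exists): features with
   two-way random-effects absolute-agreement single-rater ICC(2,1) < 0.75
   are discarded.  The estimator is the classical mean-squares form
   (MSR − MSE)/(MSR + (k−1)MSE + k(MSC − MSE)/n).
2. **z-score** with training mean/sd; constant columns dropped with a
   report entry; test rows reuse training statistics.
3. **Pearson filter**: greedy left-to-right scan dropping the later column
   of any pair with |r| > 0.9 (strict), leaving no surviving pair above the
   cutoff.
4. **LASSO**: least-squares L1 fit of the 0/1 outcome (the behaviour of the
   standard LassoCV; logistic loss would select different sets, so the
   choice is fixed and documented), penalty chosen on a 20-point geometric
   grid over [0.005, 0.05] by seeded 5-fold CV, high iteration cap and
   relaxed tolerance (1e-3).  If everything shrinks to zero the stage
   passes its input through and defers to RFE.
5. **RFE** with an L2 logistic estimator: drop the smallest-|coefficient|
   feature per round, exact ties dropping the later column, until the
   target count remains.  The target count is not published; by default it
   is chosen by stratified 5-fold CV AUC over {3, …, 10} (smaller on ties),
   and can be fixed by the caller.

Each stage's survivors are a subset of the previous stage's, and the whole
chain replays exactly from its seed.

## Models and evaluation

Model variants mirror the study design — WH, Habitats, CF, IHC and their
combinations — with combined variants concatenating selected feature blocks
and refitting one classifier (not stacking scores).  The CF block defaults
to rim enhancement + high T2 signal and the IHC block to HR negativity +
HER2 positivity (the pairs retained by the original univariate screens); a
p < 0.05 univariate screen is available for synthetic covariates.
Classifiers: L2 logistic regression (C = 1) or a linear SVM with
Platt-scaled probabilities calibrated on training folds.  Training-set
performance is summarized by stratified 5-fold CV.

Evaluation is rank-based throughout.  The AUC is the Mann-Whitney
probability with ties counted ½ (equal to trapezoidal ROC integration);
confidence intervals use the DeLong structural-component variance with a
normal approximation, clipped to [0, 1] (whether the original CIs were
DeLong or bootstrap is unstated, so this is simply the package default).
The operating point maximizes the Youden index, smallest threshold on ties;
positivity is called at score ≥ threshold everywhere, including decision
curves.  The DeLong two-model test uses midrank placement components with
the covariance of the paired components; a self-comparison returns p = 1.
Decision curves report NB(pt) = TP/n − FP/n · pt/(1−pt) on a default grid
0.01–0.60 (step 0.01) against treat-all and treat-none.

Contingency statistics default to the *uncorrected* Pearson chi-square,
which reproduces the published 2×2 statistics to three decimals; the Yates
correction is opt-in.  Continuous group comparisons use the pooled-variance
t-test after a Shapiro-Wilk pre-check on both groups, otherwise the
Mann-Whitney U with normal approximation and tie correction.

## Numerical conventions and edge cases

* MCC with a zero denominator is defined as 0.
* Equidistant cluster assignment and tied Youden maximizers resolve to the
  smallest label/threshold; RFE coefficient ties drop the later column.
* The null-data leakage control is evaluated as the mean held-out AUC over
  20 seeds (a single null AUC at n ≈ 30 has sd ≈ 0.1, so per-seed banding
  would be dominated by sampling noise).
* Problem sizes of the shipped checks: 27-point noiseless IVIM grid; one
  2 000-voxel SNR-50 phantom for habitat recovery; 450 points × B = 50 for
  bootstrap K selection; 20 seeded runs for selection sanity; 2 000 null
  replicates for DeLong calibration; a 140-patient cohort of 12×12×8-grid
  phantoms (~440 tumor voxels each) for the end-to-end run.  These sizes
  were chosen as the smallest at which the corresponding statistics are
  stable.

## Known limitations

* Equivalence with the vendor fitting toolbox cannot be asserted (its
  algorithm is undisclosed); only self-consistency properties are claimed.
* Whether the original clustering was pooled or per-patient, the exact
  bootstrap stability criterion, the RFE target count, and the final
  per-model feature lists are not published; the package documents its
  reconstructions and exposes them as configuration.
* Texture/wavelet radiomics, DICOM handling, acquisition simulation and
  anatomical realism are out of scope.
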