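# Methods

This note records the models, conventions and design choices behind the
package, in the spirit of a methods appendix: what is computed, under which
assumptions, and where the genuinely open decisions were made.

## Phantom cohort model

Each synthetic subject is a co-registered DWI/ADC pair on a small grid
(default 24×40×40 voxels) containing one infarct-like lesion.

**Geometry.** The lesion is the union of 1–3 overlapping ellipsoids with a
common scale factor bisected so the voxel count hits the requested volume
(log-uniform over 60–400 voxels by default); the largest 26-connected
component is kept. This gives controllably sized, non-convex shapes.

**Intensity.** The background is a brain-like ellipse (DWI 0.35, ADC 0.65
against 0.02 air). The lesion adds a positive DWI contrast and a negative
ADC contrast (both uniform per subject within configured ranges), plus a
Gaussian-random-field texture: unit-variance smoothed white noise whose
correlation length (0.6–2.0 voxels) is the property texture features must
detect. Global Gaussian noise (SD 0.02) approximates magnitude noise;
at these SNRs the Rician correction is negligible.

**Clinical covariates** are sampled independently to match the marginal
frequencies of a published ~1,000-patient acute-ischemic-stroke cohort
(age N(65.9, 12.4²), 68% male, TOAST subtype frequencies, secondary
prevention rates, Poisson NIHSS/mRS). Only margins are constrained — no
covariate dependence is modeled.

**Labels.** Recurrence probability is logistic:
`p_i = expit(b0 + Σ_k w_k z(f_k)_i + Σ_j c_j z(x_j)_i)` over standardized
named radiomic features and clinical covariates; the intercept `b0` is
found by 1-D root finding so the cohort mean equals the target prevalence
(0.085). Labels are drawn either independently (Bernoulli) or — the test
default — in exact-count mode (positives = round(n·prevalence), chosen by
probability-weighted sampling without replacement), which pins the
85/918 arithmetic exactly.

**Planted effect sizes.** The generator's default weights were calibrated
once, via a latent-normal Monte Carlo against the published three-model AUC
profile (clinical 0.675, radiomics 0.779, combined 0.847), so that the
*realized* arm AUCs of this pipeline land in that qualitative regime:
radiomic weights (−1.8 on lesion mean ADC, +1.2 on lesion ADC SD, +0.9 on
the LLL-band co-occurrence contrast) and clinical log-odds per SD (age
0.70, statins 0.55, anticoagulants 0.50, atrial fibrillation 0.40). These
are free knobs of the phantom, not estimates of any real population.

**What the phantom does not emulate:** anatomy, multi-lesion subjects,
scanner effects, covariate correlations, non-logistic risk. Passing tests
demonstrate the pipeline recovers *planted* signal under its own
generative assumptions — not clinical validity on real scans.

## Segmentation

Slices are windowed to [0,1] with `clip((v − (level − width/2))/width)`;
for phantoms the level/width come from per-volume p1/p99 percentiles since
no scanner windowing exists. The segmenter is a small 2D U-Net
(encoder-decoder with long skip connections) implemented in NumPy with
manual gradients; default depth 2 with 8 base channels, trained with
Adam (lr 5e-3, batch 8, 100 epochs) on BCE + soft-DICE loss. A depth-3 /
16-channel variant is available but trains slower on CPU for no accuracy
gain on phantoms (held-out median DICE 0.885 vs 0.880). Training is
deterministic given the config seed.

Post-processing follows the clinical pipeline's two rules with strict
inequalities: per axial slice, 8-connected components under 20 pixels are
deleted (too small to carry texture); if the cleaned 3D mask is under 50
voxels the subject is flagged excluded. Segmentation *accuracy* (DICE) is
measured on the raw thresholded output: small true lesions legitimately
spread below 20 pixels per slice, so cleanup is a pre-extraction step, not
part of the accuracy metric.

## Radiomic features

513 = 57 × (1 image domain + 8 wavelet sub-bands), with 57 = 18 first-order
+ 23 co-occurrence + 16 run-length features. The exact identity of the 39
texture features is a documented reconstruction constrained by the printed
counts; the counts, not the identities, are the structural contract.

- **Sub-bands**: one-level stationary (undecimated) 3D wavelet transform,
  Haar by default (chosen so constant volumes give exactly zero detail
  bands); shape-preserving, so the lesion mask applies unchanged. Odd
  extents are edge-padded to even and cropped back.
- **First-order** (18): mean, median, min, max, range, variance, SD,
  skewness, excess kurtosis, energy, histogram entropy and uniformity
  (32 fixed-width bins over the observed range), p10, p90, IQR, MAD,
  robust MAD (p10–p90), RMS. Zero-variance conventions: skewness =
  kurtosis = 0, entropy = 0, uniformity = 1 (with a relative 1e-12 SD
  epsilon against summation rounding).
- **Texture**: gray levels quantized to 32 equal-width bins over the
  mask's min–max (constant region → single level). Co-occurrence counts
  are accumulated over the 13 distance-1 directions of the
  26-neighborhood, symmetrized and direction-summed before the 23 features
  are computed; run-length matrices are computed per direction and
  direction-averaged before the 16 features. A single-voxel mask
  degenerates to the constant-region conventions (contrast 0,
  inverse-difference features 1).
- Masks below 50 voxels raise an exclusion error, mirroring the cohort's
  inclusion rule.

Invariants verified by tests: joint whole-voxel translation leaves all
features unchanged; adding a constant shifts location features by that
constant and leaves dispersion and (min–max-quantized) texture unchanged;
longer texture correlation length raises co-occurrence correlation.

## Feature selection

The L0-penalized least-squares objective is solved exactly by subset
enumeration when p ≤ 12 and by greedy forward selection (orthogonal
matching pursuit with least-squares refit on the support) beyond; the
exact path makes the solver provably optimal on the small instances where
an exhaustive oracle is computable, and the greedy path is validated for
planted-support recovery at realistic sizes. Labels are coded −1/+1 and
regressed directly, as the objective implies. Both budgets are accepted
(η or a support-size cap; the cap wins if both are given). Importance is
|w_j|; top-K (default K=100) with ties broken toward the lower index.
Clinical covariates enter as 6 standardized columns appended to the 513
radiomic columns, so the selected set can mix modalities.

## Classifier arms

- **Clinical**: lightly L2-regularized logistic regression on the 6
  clinical covariates (age, statins, anticoagulants, antiplatelets,
  atrial fibrillation, NIHSS), standardized internally.
- **Radiomics**: single-layer GRU (hidden 64) over the 9×57 sequence
  (image domain first, then LLL…HHH), final hidden state → affine →
  2-class softmax. Features are standardized with training-set statistics;
  positions not chosen by selection are zero-masked rather than re-packed,
  preserving the sequence layout. Loss is class-weighted cross-entropy
  (weights inverse to training class frequencies by default); Adam with
  lr 1e-4 and batch size 10; up to 200 epochs with early stopping on a
  10% validation split (patience 30, best weights restored).
- **Combined**: the clinical block joins as a zero-padded 10th time step
  and is never masked by selection.

The under-sampling split draws the requested 57 positives / 100 negatives
into training uniformly without replacement; all remaining subjects form
the test cohort (846 with 28 positives at the default cohort).

## Evaluation

AUC uses the Mann-Whitney pair-counting estimator with the ½-tie
convention; 95% CIs come from the DeLong variance on the logit scale.
The DeLong test compares correlated AUCs through the covariance of their
structural components; a zero-variance difference (e.g. identical scores)
returns p = 1 by convention. Operating thresholds for accuracy/
sensitivity/specificity are Youden-optimal on training predictions and
applied to the test cohort. Decision curves report
NB(t) = TP/N − (FP/N)·t/(1−t) against treat-all and treat-none on a
strictly-increasing grid inside (0,1).

Cohort tables use: pooled Student t for age-like normal variables (the
Welch variant is exposed), Mann-Whitney for ordinal scores (exact
permutation enumeration when n1·n2 ≤ 400 and the combination count is
enumerable, tie-corrected normal approximation otherwise), and for
categorical variables uncorrected Pearson χ² when all expected counts are
≥ 5, Fisher's exact test on sparse 2×2 tables. P-values format to three
decimals, "<0.001" below. These conventions reproduce the published
cohort-table p-values (sex 0.662, statins 0.004, age 0.003) from the
printed counts.

## Problem sizes and numerical choices

Desk-scale study sizes, chosen once: phantom volumes 24×40×40; the
segmentation study trains on 15 subjects' lesion slices and evaluates 20
held-out subjects; the arm-ordering study runs the full n=1003 cohort with
the 57/100 split over 10 seeds; oracle checks use m ≤ 12, p ≤ 10 (L0) and
n = 30 with 10,000 bootstrap draws (DeLong). All randomness flows from
explicit integer seeds; the pipeline fans a master seed out to per-stage
seeds by fixed offsets so stages can be rerun in isolation. Probabilities
in the weighted cross-entropy are clamped at 1e-12; lesion-scale bisection
runs 40 iterations; ranking ties break toward lower indices everywhere.

## Known limitations

The 39 texture-feature identities are a reconstruction; the recurrent
network's topology and sequence construction are package decisions (the
source method names none); clinical covariates are independent in the
phantom, so interactions between risk factors are absent; the combined
model's advantage over radiomics alone is small (as in the published
profile, where their difference was not significant), so single-seed
orderings of those two arms can be close.
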