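# Methods

## Problem setting

High-risk breast-cancer screening produces annual contrast-enhanced MRI
volumes that are overwhelmingly negative. Radiologists read them by comparing
against the previous visit; the machine analogue is to model the *normal*
variability of inter-visit change and flag deviations. This package analyses
difference volumes `I_diff = I_i − I_j` of consecutive negative (grade-1)
visits: an anomaly in such a difference is, by construction, a signal present
*before* any lesion is reported, and the scientific question is whether it
predicts lesion emergence at a later visit — locally (at the future lesion
site) and globally (per examination).

## Anomaly model

The model of normal appearance change is a reconstruction-based
anomaly detector in the f-AnoGAN family, trained in two stages on patches
from the training split's negative subjects only:

1. **Adversarial stage.** A generator `G: z → x̂` (latent dimension 8–128,
   configurable) and a critic `D` are trained with the Wasserstein objective;
   the critic is regularized by weight clipping (bound `c = 0.05`) and takes
   5 updates per generator update. Networks are small dense nets
   (two hidden layers, LeakyReLU 0.2, tanh output for `G`) with explicit
   numpy backpropagation and Adam (lr 1e-4, β₁ = 0, β₂ = 0.9) — at 64-pixel
   patches, convolutional capacity is unnecessary and plain numpy keeps the
   whole pipeline dependency-light and bit-reproducible. Weight clipping
   rather than a gradient penalty regularizes the critic; it is the original
   Wasserstein formulation and avoids double backpropagation, which explicit
   gradients make disproportionately error-prone.
2. **Encoder stage.** With `G`, `D` frozen, an encoder `E` minimises the izif
   objective `mean[(x − G(E(x)))²] + κ·mean[(f(x) − f(G(E(x))))²]`, κ = 1,
   where `f(·)` is the critic's penultimate-layer activation. Gradients flow
   through the frozen networks into `E` only.

**Scoring.** `L(x) = L_R(x) + k·L_D(x)` with `k = 0.1`;
`L_R = mean[(x − y)²]`, `L_D = mean[(f(x) − f(y))²]`, `y = G(E(x))`. Means
(not sums) over pixels/features make the score independent of patch size.
`L ≥ 0` always, `L = 0` exactly when reconstruction and features match, and
`L` is non-decreasing in `k` whenever `L_D > 0`.

A practical note on the critic: the Wasserstein objective guarantees only
that real patches outscore *generated* ones. The clipped critic keys heavily
on variance-like features, so far-out-of-distribution inputs (e.g. uniform
noise) can receive arbitrarily high "realism" scores. The critic's
contribution to anomaly detection is therefore exercised through the feature
term `L_D` and the encoder objective, not through its raw score on arbitrary
inputs.

## From patches to examinations

* **Patch extraction.** Axial 2-D patches (side `p`, default 64; 8 at desk
  scale) with centers inside the breast mask; a patch is discarded when more
  than 50 of its pixels fall outside the mask ("background"), applied
  uniformly to normal and future-lesion patches. Future-lesion patches are
  centered on voxels of the annotated lesion mask, subsampled to 20–40 per
  subject, and cut from the *last negative/negative* difference — the exam in
  which a precursor, if any, must live.
* **Normalization.** Affine map of the training split's 1st–99th intensity
  percentiles to [−1, 1], clipped; statistics come from the training split
  only.
* **Anomaly maps.** Windows slide per axial slice on a stride grid (top-left
  corners at multiples of the stride, window fully inside the slice); a
  window is evaluated iff its center voxel is in the mask. Each voxel's value
  is the mean of all covering windows — the least-assumptive symmetric
  fusion, and the one an exhaustive-enumeration oracle can verify exactly.
* **Examination score.** Voxels with map value strictly above the patch
  threshold are "anomalous"; the exam score is the anomalous fraction of
  covered breast-tissue voxels, hence in [0, 1]. The patch threshold is the
  mean Youden threshold over the validation bootstrap ROC replicates.
* **Lesion-level call.** A future lesion is "detected" when at least 50 % of
  the patches covering its location score above the patch threshold.

## Statistical evaluation

* **ROC / Youden.** Empirical ROC over all distinct score thresholds with the
  `score > t` convention; trapezoidal AUC (equal to the Mann–Whitney
  statistic, ties at half credit). Youden's `J = sens + spec − 1` is
  maximised over midpoints between adjacent distinct scores plus sentinels
  outside the range; ties break toward the higher (more specific) threshold.
  These conventions are frozen so that exhaustive-search oracles match to
  machine precision.
* **Bootstrap.** 128 patches per cohort per replicate (without replacement
  within a replicate; a documented fallback samples with replacement when a
  pool is smaller), 10 replicates, percentile 95 % CIs per metric.
* **Examination level.** Maximum-likelihood logistic regression of
  future-lesion presence on exam score plus a scanner-era indicator (1 if
  either visit of the difference pair is from the shifted era). Wald
  `z = β/SE` with two-sided normal p, α = 0.05. Complete or quasi-complete
  separation is flagged as non-convergent (coefficient or SE magnitude
  checks after a Newton-then-BFGS fit) rather than reported as a spurious
  result. A sweep over `T_exam = 0.1 … 0.9` reports
  sensitivity/specificity/PPV/NPV, also under the grade regrouping 1–2 vs
  3–5 (empty strata yield NA tables).

## Synthetic study conditions

The generator emulates the *statistical* structure the analysis assumes, not
breast anatomy:

| parameter | default (desk scale) | role |
|---|---|---|
| volume shape | (6, 32, 32) voxels | axial stack, z thinnest |
| breast mask | squircle prism, semi-axes ≈ 0.46·extent | keeps corner background low for centered patches |
| texture | Gaussian random field, corr. length 3 vox, amplitude 0.25 around base 0.5 | fibroglandular stand-in |
| inter-visit change | smooth warp ≤ 0.5 vox + global drift σ = 0.01 + iid noise σ = 0.02 | "normal variability" |
| scanner shift | first visit, prob. 0.3: `v → 1.15·v + 0.08` | era confound (false-positive mechanism) |
| lesion | Gaussian bump, peak 0.7, σ = radius/1.6, final visit | the emerged finding |
| precursor | same center, peak 0.2, σ = 1.5·radius, visit n−1 | the learnable early signature |

Cohort presets: `smoke_config` (24 negative + 16 positive subjects; fast
demos and bit-reproducibility checks) and `study_config` (60 + 40,
≈ 70 evaluable examinations; all recovery and association analyses). Splits
follow the screening design: negatives 75/7/18 % train/validation/test,
positives 15/85 % validation/test.

The precursor amplitude was calibrated once, at design time, to the regime
the method is meant for: patch-level AUC around 0.75–0.9 rather than 1.0, so
that the Youden threshold falls *inside* the normal score distribution and
examination scores of the two cohorts overlap. With a much stronger
precursor the exam-level logistic fit quasi-separates (Hauck–Donner effect:
exploding coefficients, uninformative Wald p) — a small-sample pathology of
the Wald test, not of the method. The evaluation cohort size of
`study_config` was likewise chosen so the asymptotic Wald test is in its
calibrated regime; the package verifies this directly (below).

What the generator does **not** emulate: contrast kinetics, anatomy (ducts,
vessels, chest wall), spatially varying noise, partial-volume effects, or
reader variability in lesion annotation. Passing tests therefore show that
the *pipeline* recovers planted signals under the stated statistical
structure — they are not evidence about clinical data.

## Null calibration

With lesion and precursor contrast set to zero the cohorts are statistically
identical, so the Wald test on the exam-score coefficient should reject at
its nominal level. `diffanomaly.calibration.null_calibration` simulates 400
small cohorts (80 exams each), scores every exam with a *fixed* untrained
network (valid under the null, where labels are independent of any
label-blind scoring function; the per-cohort voxel-score median serves as
the threshold), fits the scanner-adjusted logistic model, and checks the
empirical rejection rate against the 99 % binomial band around 0.05. Each
subject contributes its first inter-visit exam so that both cohorts can
carry the scanner flag — otherwise the covariate itself would be separable
by construction.

## Numerical conventions and edge cases

* All randomness flows through `numpy.random.SeedSequence` fan-out (per
  subject via CRC of the subject id, per stage via fixed keys), so results
  are independent of cohort ordering and bit-reproducible; the pipeline
  report carries a SHA-256 content hash.
* Registration is SimpleITK rigid-then-affine (correlation metric, regular
  sampling); its quality score is the masked normalized cross-correlation
  after resampling. If the optimised transform scores below the identity
  alignment the identity is kept — the visits already share a grid, and an
  optimiser excursion must not corrupt difference volumes. Quality below the
  configurable floor (default 0.85) excludes the subject with reason code
  "excluded: misregistration".
* Segmentation (when generator masks are not passed through): Otsu threshold,
  largest connected component, morphological closing; empty results exclude
  the subject.
* Exams are called positive iff score strictly exceeds the threshold;
  boundary cases are covered by tests (background = 50 kept, 51 dropped;
  lesion fraction exactly 0.5 counts as detected).
* Degenerate inputs fail loudly with named errors: zero-variance
  normalization bounds, empty masks/pools, single-class ROC input,
  non-finite losses or scores.

## Known limitations

* The anomaly score scale is model- and normalization-bound; thresholds do
  not transfer between trained models.
* The mean-fusion sliding window blurs localized signals at large overlaps;
  stride defaults keep fusion mild.
* Dense networks cap out at small patches; at 64×64 and beyond, training
  time grows quickly even though the method is unchanged.
* The Youden threshold inherits the (by design, small) validation split's
  sampling noise; with very few validation subjects the examination-level
  operating point varies between runs — visible in the smoke preset,
  averaged out at study scale.
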