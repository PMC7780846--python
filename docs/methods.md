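# Methods

## The analysis in brief

The package studies whether a binary group label (sex at birth; girl = 1,
boy = 0) can be predicted from registered 3D T1-weighted brain volumes,
and — more importantly — *where* in the volume the predictive signal lives
once confounded signal is removed. The pipeline has five stages:

1. **Prediction.** A convolutional *extractor* maps each volume to M
   continuous predictor variables **P**; a fully connected *classifier*
   reduces **P** to a prediction score **S** = P(girl). Both are trained
   end-to-end with binary cross-entropy. Each subject contributes two
   training samples — the volume and its left–right mirror — because the
   group effects of interest are assumed bilateral; at test time **S** is
   the average of the two hemisphere-copy scores.
2. **Evaluation.** Subject-level, sex-stratified 5-fold cross-validation.
   Training folds are oversampled to a fixed per-class count with small
   random rigid transforms (translations within 1 voxel, rotations within
   1° per axis); the held-out fold is never augmented. Metrics: balanced
   accuracy, TPR, TNR, FPR, and AUC (pairwise concordance with ties at ½).
3. **Confounder screen.** After retraining on the full cohort, each
   predictor P_j is fit with an OLS GLM
   `P_j = β0 + β1·S + β2·z_pds + β3·z_age + β4·z_ses`.
   A predictor with p ≤ 0.05 (uncorrected, deliberately lenient) on any
   confounder coefficient is *confounded*. Conditioning on **S** keeps
   predictors that merely track the class signal from being flagged via
   the confounder–class correlation.
4. **Saliency.** Per-subject maps are |∂(pre-sigmoid score)/∂voxel|,
   averaged over the two hemisphere copies (the mirrored copy's gradient
   is mirrored back), min–max scaled per map, then averaged across
   subjects. Gradient flow is restricted by a stop-gradient mask at the
   predictor layer: unflagged predictors give the *confounder-free*
   pattern, flagged ones the *confounded* pattern (optionally restricted
   to predictors attributed to one confounder by their minimum p-value).
   ROI statistics aggregate each subject's mean saliency per atlas label,
   compare sexes with pooled two-sample t-tests, and Bonferroni-correct
   over ROIs.
5. **Downstream statistics.** Cohen's d from group summaries (pooled SD
   with n−1 weights), Pearson correlations of **S** with cognitive
   scores, a three-condition partial-mediation analysis, χ² tests of
   pubertal stage between always-correct and always-wrong subjects across
   repeated CV runs, per-PDS-stratum accuracy, classical classifiers on
   ROI features under the same CV protocol, and DeLong's test for
   correlated ROC curves.

## Network architecture

The engine is a small explicit-backprop implementation (numpy) because the
pipeline needs input gradients and per-predictor stop-gradients, and must
be bit-reproducible under a seed. Default architecture for a 16³ grid:

- one 3×3×3 conv block (8 channels, leaky-ReLU slope 0.01, 2× average
  pooling), giving an 8³ feature grid;
- a **local predictor readout**: a 1×1×1 convolution to 1 channel, so
  M = 512 predictors, one per spatial cell. Each predictor summarizes one
  receptive field (≈4 voxels wide). This locality is load-bearing: the
  per-predictor GLM screen can only separate a class effect in region A
  from a confounder effect in region B if different predictors cover the
  two regions. A dense readout (a linear map of the flattened feature
  grid, also available as `predictor_mode="dense"`) converges to predictors
  that all mix both regions, which makes every predictor screen as
  confounded. Globally pooled channels are worse still — translation
  invariance makes them provably unable to distinguish *where* an
  intensity effect sits;
- a classifier with one hidden layer (16 units, leaky ReLU) and a sigmoid
  output. The leak matters: with a plain ReLU an occasional training run
  collapsed into a dead hidden layer (constant logit).

Training: Adam (lr 3e-3), batch 32, binary cross-entropy, an L1 penalty
(1e-4) on the predictor-readout weights, 5–12 epochs depending on the
experiment (the synthetic tasks are strongly separable, so short budgets
suffice; each experiment states its epoch count). Saliency uses the
pre-sigmoid score: the sigmoid's derivative collapses for saturated
scores, and the pre-activation gradient gives the same voxel ranking
without that attenuation. Saliency magnitudes are absolute values so that
averaging across subjects cannot cancel signed contributions.

## Synthetic cohorts

The generator builds what the analysis assumes rather than what a brain
looks like: a radial phantom (interior 1.0, bright shell 1.5, background
0) with five bilateral spherical ROIs (radius 0.1·grid) mirrored across
the left–right axis, plus i.i.d. Gaussian voxel noise (SD 1.0 by
default).

Covariates emulate a 9–10-year-old cohort: age 9.92 ± 0.62 (girls) /
9.95 ± 0.62 (boys); PDS 2.0 ± 1.0 (girls) / 1.3 ± 0.6 (boys), clipped to
[1, 5] — the PDS sex gap (point-biserial r ≈ 0.4) is what makes PDS a
genuine confounder; SES 18 ± 67 (an arbitrary continuous index); head
size ≈ 1342 ± 16 cm³. A latent class axis L = (2·sex − 1) + N(0, 0.5)
underlies mediator-linked effects and cognitive scores.

Effects are injected per subject as `magnitude · noise_sd · x_i` over a
region, with the driver value x_i centred: ±0.5 for sex (so `magnitude`
is the between-class mean difference in noise-SD units) and z/2 for
continuous drivers (so a 2-SD swing of the driver matches the sex-effect
convention). `volume_scale` effects dilate/erode the region sphere by a
driver-dependent fractional volume change while rescaling the added
contrast to conserve total added intensity — a pure shape cue that leaves
fixed-atlas ROI means unchanged, which is what lets the voxel-level model
beat ROI-feature baselines.

Cognitive scores are drawn per sex from configurable (mean, SD) pairs
whose defaults match a published pre-adolescent battery; a
`mediation_link` coefficient adds `coef · L` to one named test, creating
the partial-mediation structure the downstream analysis detects.

What the generator does **not** emulate: anatomy, scanner artifacts,
registration error, spatially correlated noise, nonlinear covariate
effects. Passing recovery tests therefore shows the *machinery* is sound
(effects are found where they were injected, confound removal removes
what it should), not that the real-data findings replicate.

## The recovery experiment and its failure physics

The headline synthetic experiment plants a sex effect (magnitude 3) in
region 1 and a PDS-driven effect (magnitude 3) in region 4 of a 400-
subject, 16³ cohort. The two regions are deliberately non-adjacent (≈6
voxels apart): receptive fields of predictors at one region's edge must
not overlap the other region, otherwise genuinely mixed predictors arise
whose confounder correlation is real, not type-I error.

The confounder-free pattern recovers region 1 essentially always (the
clean predictor set keeps the strong sex cells and drops the PDS cells;
the region-1/region-4 saliency ratio typically exceeds 50). The
*confounded* pattern is intrinsically noisier: with three uncorrected
tests at α = 0.05 the screen falsely flags ≈14 % of clean predictors, and
whenever one of the handful of strong region-1 predictors is among them,
per-map min–max scaling normalizes every subject's map to that cell and
region 1 can outrank region 4 in the confounded average. With ~5 strong
region-1 cells the chance of at least one false flag is ≈ 1−0.86⁵ ≈ 50 %
per replicate, irreducible at the mandated α. The PDS-specific pattern
(flagged predictors whose minimum p-value belongs to PDS) cuts the
contamination probability by ~3× and is the variant the acceptance
experiment reports alongside the pooled pattern.

## Statistical conventions and numerical choices

- **Cohen's d**: |Δmean| / pooled SD, (n−1)-weighted; this reproduces the
  published cognitive-battery values to their printed precision.
- **χ²**: Pearson's formula without Yates correction (tables are k×2 with
  large n); adjacent ordinal levels are pooled while any expected count
  is below 1.
- **Mediation condition 3**: the statistic is
  |r(sex, S)| − |partial r(sex, S | mediator)|; the null permutes the
  mediator column; p uses the add-one rule (1 + #{≥ observed})/(1 + B).
  The published protocol fixes only the permutation count (10 000); the
  statistic and scheme are this package's construction.
- **DeLong**: structural-components estimator; the AUC inside it is the
  same placement-value computation as `compute_metrics`, so the two paths
  agree exactly; identical score vectors short-circuit to z = 0, p = 1.
- **Ties**: scores binarize at 0.5 with ties to class 0; AUC counts ties
  as ½.
- **Degenerate inputs**: constant covariate columns raise a named
  degenerate-design error; constant saliency maps scale to all-zeros;
  empty ROIs are excluded with a warning; an all-flagged screen makes the
  confounder-free pattern an error rather than an empty average.
- **Determinism**: every stochastic step takes a seed or Generator;
  cross-validation derives per-fold seeds from the run seed; regenerating
  a cohort from the same seed is bit-identical.

## Problem sizes

Experiments run on 16³ grids with cohorts of 200–400 subjects and the
compact default architecture; these sizes keep every recovery experiment
and calibration (hundreds of Monte-Carlo replicates, thousands of
screened predictors) comfortably reproducible on a single CPU. The same
code accepts 64³ volumes and deeper conv stacks through `ModelConfig`;
nothing in the pipeline is specific to the reduced scale.

## Mediation at desk scale

On the strongly separable synthetic cohorts the trained model's score
saturates to the class label, which leaves no within-class score variance
for a mediator to explain: condition 2 of the partial-mediation analysis
is then correctly non-significant, and the analysis driver reports "no
mediation" on the demonstration cohort. The mediation machinery itself is
validated on constructed data where the score retains a continuous latent
component (sex = threshold(latent), S = latent + noise, mediator =
latent + noise): there the three-condition verdict fires with power above
0.8 at n = 1000, and its condition-2 test holds its nominal level under a
null mediator. Detecting mediation through a *trained* score requires a
cohort where the model is imperfect — which is precisely the real-data
regime.

## Known limitations

- The numpy engine is CPU-bound and meant for desk-scale grids; a
  GPU-backed reimplementation of the same interfaces would be needed for
  64³ cohorts of thousands of subjects.
- The screen is linear; a confounder acting nonlinearly on a predictor
  can evade it.
- The confounded pattern's sensitivity to chance flags (see above) is a
  property of the published screening rule, not of this implementation.
- Real-data stages (NIfTI ingestion, atlas ROI statistics) are
  implemented but exercised only on synthetic cohorts; upstream
  registration/skull-stripping is out of scope.
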