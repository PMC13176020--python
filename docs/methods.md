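# Methods

This note documents the models and procedures the package implements, the
defaults and why they were chosen, what the synthetic generator does and does
not emulate, and the numerical conventions that make results bit-reproducible.

## Data model

A *tooth* is the analytical unit: one ICDAS score 0–4 (collapsed to sound /
initial / moderate), and an unordered set of exactly five CIELAB readings at
named occlusal sites (two buccal cusp slopes, two mesial cusp slopes, the
central pit). Site readings are repeated measurements of the tooth, never
independent samples: they travel together through splitting, enter the models
as a set or a flattened block, and are resampled together in the bootstrap.

## Synthetic cohort generator

The generator emulates the structure a spectrophotometric caries dataset
must have for this analysis to be meaningful:

* **Composition.** 300 teeth, 40 sound / 181 initial / 79 moderate by
  default — the class imbalance the evaluation machinery has to cope with.
  Within initial and moderate, the specific ICDAS integer (1/2, 3/4) is
  assigned uniformly at random; the pipeline only consumes the 3-category
  label and the two binary contrasts derived from it.
* **Color model.** Each tooth draws a base color from its category mean with
  Gaussian between-tooth scatter (`tooth_sd`); in carious teeth,
  `n_lesion_sites` (default 2) randomly chosen sites receive an additional
  lesion shift, scaled ×1 for initial and ×2 for moderate; every reading gets
  i.i.d. Gaussian measurement noise per channel, and L\* is clipped to
  [0, 100] (clip rather than resample, for determinism).
* **Defaults.** Severity decreases L\* and increases b\* (white-spot/brown
  direction): category means (74, 2, 16), (72, 2.5, 17.5), (69.5, 3.2, 20);
  `tooth_sd` (3.5, 1.2, 3.0); lesion shift (−3, 0.8, 2); noise SD 2.0;
  seed 42. No per-class CIELAB summary statistics are available to copy, so
  the absolute values are stipulated. They were fixed once so that the
  between-class separation is of the same order as the within-class scatter:
  severity is recoverable well above chance but classification is not
  trivial, and the set-based neural families outperform the tree ensembles —
  the qualitative regime the pipeline is designed to probe. Under this
  default, test balanced accuracy lands around 0.55–0.8 depending on family
  and seed.

**What passing tests on synthetic data do and do not show.** The generator is
Gaussian with a single severity-scaled shift direction; real enamel color is
affected by staining, fluorosis, tooth type, surface moisture and device
effects, none of which are simulated (heavier tails can be added through the
config). Tests on these cohorts verify that the *machinery* — leakage-safe
splitting, feature engineering, imbalance handling, calibration, clustered
inference — is correct, not that any particular accuracy is attainable on
real teeth.

## Colorimetric features

Per tooth: mean L\*, a\*, b\*. Per site: deviations from the tooth mean
(ΔL\*, Δa\*, Δb\*, which sum to zero over the five sites by construction),
chroma C\* = √(a\*² + b\*²), hue angle h = atan2(b\*, a\*) in degrees mapped
to [0, 360) with (0,0) → 0 by convention, ΔE versus the tooth's own mean, and
ΔE versus the *sound reference* — the channel-wise mean color over all site
readings of sound-category teeth **in the training partition only**. A split
whose training partition contains no sound tooth is an error whose remedy is
re-splitting, never borrowing teeth from validation or test.

ΔE uses the CIE76 Euclidean form √(ΔL² + Δa² + Δb²): the canonical default in
dental color science, and the only form consistent with the ΔL/Δa/Δb
decomposition reported alongside it. CIEDE2000 would be a config-level
extension, not a replacement. Chroma and hue are computed on the raw site
a\*, b\* (not on deltas): they describe each site's own color.

The flattened per-tooth vector is 3 means + 5 sites × 7 features = 38
columns, in fixed site-label order.

## Splitting

Group-stratified hold-out at the tooth level: within each category, teeth are
shuffled under the seed; round-half-up of `count × test_frac` go to test,
then round-half-up of `remaining × val_frac` to validation, rest to train.
Any global surplus/deficit against the round-half-up total is corrected in
the largest category. This rule is fixed for determinism; with 40/181/79 and
a 10% test fraction it yields the 4/18/8 test composition. The neural
families use the validation partition for early stopping and calibration;
the tree families train on train + validation (they regularize internally)
— both read only non-test teeth.

## Classifier families

* **Tree ensembles** (random forest, XGBoost, LightGBM — three
  complementary flavours of bagged/boosted axis-aligned trees) consume the
  flattened vectors with inverse-frequency class weights
  w_k = N/(K·n_k) (count-weighted mean 1), 500 estimators, library-native
  regularization (learning-rate control, L2, subsampling). A row-per-site
  alternative with tooth-level probability averaging is available via
  `input_mode="site"`.
* **MLP**: two ReLU hidden layers (64, 32) on the standardized flattened
  vector, inverted dropout 0.3, Gaussian input noise SD 0.05 (on
  standardized inputs), focal loss with γ = 2 and the same class weights.
* **Deep Sets**: a shared encoder (32, 32) embeds each site's 10-vector
  (7 site features + the 3 tooth means as context); embeddings are pooled by
  attention — softmax over a learned scalar score per site — and a head (32)
  produces logits. Pooling is a convex, symmetric combination, so tooth
  predictions are *exactly* invariant to site order (verified over all 120
  permutations).

Both neural nets are a compact numpy implementation: full-batch Adam
(lr 0.01), reduce-on-plateau halving after 10 stalled validation epochs,
early stopping with patience 20 on validation focal loss, best parameters
restored, max 600 epochs, all randomness from one seeded generator. At these
problem sizes (hundreds of teeth, tens of features) full-batch training is
fast and bit-reproducible. The focal loss floors p_y at 1e-12.

Layer sizes and γ were fixed once at small-data-appropriate capacity; every
value is exposed on `TrainingPolicy`.

## Calibration

Temperature scaling only — a single scalar T > 0 minimizing validation NLL of
softmax(logits/T), found by bounded 1-D minimization over log T (tolerance
well below 1e-6). It is the minimal post-hoc method whose argmax-preserving
property keeps classification metrics untouched. Tree outputs are left
uncalibrated. ECE uses 10 equal-width bins on the max-probability confidence;
bin count and width convention are config-exposed. A single-class validation
set leaves T unidentifiable (NLL is minimized by T → 0) and is an error.

## Evaluation and inference

All metrics are tooth-level. Multiclass: accuracy, balanced accuracy
(primary, under imbalance), macro-F1 (a class with zero true and zero
predicted positives contributes F1 = 0), per-class one-vs-rest SE/SP, OVR
AUC per class and macro. Binary contrasts collapse the simplex: *early* score
= p(initial) + p(moderate), *operative* score = p(moderate); SE/SP use a 0.5
operating point (config-exposed; no threshold is canonically fixed for these
contrasts), AUC is threshold-free with midrank tie handling (equal to the
normalized Mann–Whitney statistic).

Confidence intervals are percentile clustered-bootstrap: resample teeth with
replacement B = 1000 times, recompute, take the 2.5/97.5 percentiles.
Percentile (not BCa) keeps the method as simple as its description; under
heavy imbalance a percentile CI can exclude the point estimate, which is
expected and not "repaired". Resamples on which a metric is undefined (a
class absent) are skipped and counted; more than 50% skips aborts as
unstable. Note the percentile interval for small-n means covers slightly
below nominal (~93–94% at n = 40) — inherent to the method, not a defect.

Paired comparisons: McNemar's exact two-sided binomial test on discordant
counts (p = 1 when there are none); DeLong's test via midrank placement
values with two-sided normal p (identical placements → ΔAUC 0, p = 1 by
convention), Holm step-down adjustment across comparisons; Wilcoxon
signed-rank with the exact distribution for ≤ 25 untied nonzero pairs and the
tie/continuity-corrected normal approximation above. The DeLong
implementation agrees with R's pROC to printed precision and with an exact
permutation oracle away from the null; near the null the asymptotic p can
differ from the exact permutation p by several percentage points at n = 40.

Per-contrast ΔAUC is reported against the best model for that contrast
(best model's Δ = 0).

## Learning curves

Each family is retrained on 50%, 75% and 100% of the non-test teeth,
subsampled group-stratified per category (round-half-up), with the
validation subset and the sound reference re-derived inside each subsample —
no preprocessing ever sees teeth outside the subsample's training portion.
Subsamples at different fractions are independent (not nested). At fraction
1.0 the subsample is the whole pool, so the primary split is reused verbatim:
the full-data cell *is* the primary model, which anchors the deltas. The
reported Δ is balanced accuracy at 1.00 minus balanced accuracy at the
fraction (exactly 0 at 1.00); the metric and sign convention are fixed here
and labelled in outputs. The test set is the fixed test partition for every
cell.

## Problem sizes and determinism

The default conditions are 300 teeth; the verification suite additionally
uses small cohorts (tens of teeth) for I/O and error-path tests, a
wide-separation zero-noise cohort on which every family must classify
perfectly, 2000-replicate Monte-Carlo checks for bootstrap coverage and
permutation agreement, and B in the hundreds where a CI's width is not
itself under test. Every stochastic component — generator, split, model
initialization, dropout/noise streams, bootstrap, subsampling — draws from
explicitly seeded generators, so any run is reproducible from its config and
seed alone.

## Known limitations

* The generator's Gaussian, single-shift-direction color model understates
  the messiness of real enamel optics (staining, fluorosis, tooth-type
  effects, device noise structure).
* Hold-out evaluation on ~30 teeth gives wide intervals, and metrics for the
  4-tooth sound class are especially volatile; the clustered bootstrap
  reports this honestly rather than hiding it.
* No cross-validation harness, no RGB↔CIELAB conversion, no image-based
  baselines, no hyperparameter search: the surface is the pipeline itself.
* Binary-contrast SE/SP depend on the 0.5 operating point; threshold-free
  AUC is reported alongside for that reason.
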