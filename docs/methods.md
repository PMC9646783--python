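# Methods

## The classification problem

Active antibody-mediated rejection (ABMR) of a kidney allograft injures the
graft's microvascular endothelium. On immunohistochemistry, markers such as
WARS1, TYMP and GBP1 produce a *microcirculation staining pattern*: brown
(DAB) positivity of endothelial rims in glomerular and peritubular
capillaries, diffuse or focal. Differential diagnoses instead show
interstitial inflammatory-cell clusters, tubular staining, or no staining at
all. `microstain` implements a two-stage, weakly supervised classifier of
whole-slide immunostain images for the binary call ABMR vs other diagnosis,
together with the validation protocol and reader-comparison statistics that
such a study needs.

## Pipeline

1. **Tiling.** The annotated parenchyma (ROI polygons, QuPath-style GeoJSON)
   is cut into non-overlapping square tiles (default 512 px; 64 px at desk
   scale) on a grid anchored at the ROI bounding-box top-left, enumerated
   row-major with 1-based consecutive indices. A tile is kept iff at least
   `min_tissue_fraction` (default 0.5) of its pixel centers fall inside the
   ROI. The index order is the only ordering the pipeline creates, and it is
   the order consumed by the 1-D pooling below.
2. **Model 1 — tile CNN.** Backbone (head removed) → global average pooling
   → one sigmoid unit. Every tile inherits its slide's label (weak labels;
   no tile-level ground truth exists). Training uses a class-weighted binary
   cross-entropy with weights `w_c = N / (2 N_c)`, augmentation (horizontal
   and vertical flips, rotation uniform in ±90°, per-channel intensity
   shifts uniform in ±0.1) on training batches only, and a two-phase
   schedule: one epoch with all convolutional layers frozen, then ten epochs
   with the last two blocks unfrozen at a lower rate, restoring the weights
   of the epoch (from either phase) with the best validation AUC.
3. **Model 2 — slide forest.** The ordered tile probabilities of one slide
   are compressed into 12 variables: mean, median, min, max, sample SD, q25,
   q75 of the raw series, plus min, max, q25, q75 and SD of the series after
   1-D average pooling (pool 10, stride 5, valid windows; a series shorter
   than the pool collapses to its single overall mean — zero padding would
   fabricate low predictions). A 100-tree random forest classifies the
   vector per patient. Validation metrics are means over 50 independently
   seeded forest fits; only the forest seed varies between iterations. The
   operating point is the closest-top-left ROC threshold (minimise
   `(1−TPR)² + FPR²`; ties break toward lower FPR, then higher threshold).
4. **Cross-validation.** Stratified (by label) group (by patient) 3-fold
   plans, repeated 5 times with reshuffles (`StratifiedGroupKFold`,
   shuffled, seeded per repeat — the same fold-construction routine the
   protocol names). Within a (repeat, fold), model 1 is trained on
   training-fold tiles with the validation-fold tiles as its model-selection
   set — a deliberate fidelity choice that accepts the optimistic bias of
   having no separate holdout; model 2 is trained on training-fold slide
   features only. Aggregation order: fold metrics are combined within a
   repeat (Se/Sp as weighted means, weights = validation-fold class sizes;
   AUC as a plain mean), then repeat-level values are averaged, with the
   sample SD across repeats reported for the AUC. Reporting rounds AUC to
   two decimals and Se/Sp to integer percent, halves away from zero.
5. **Grad-CAM.** For a chosen conv layer (default: the last), channel
   weights are the spatial means of the logit gradient; the map is the ReLU
   of the weighted feature-map sum, normalised by its maximum (an all-zero
   map stays zero), bilinearly upsampled and overlaid blue→red at alpha 0.4.

## The neural-network engine

No deep-learning framework is part of this package's dependency set; the
tile CNN runs on a purpose-built numpy engine (`microstain.nn`): im2col
3×3 same-padding convolutions, 2×2 max pooling, global average pooling, a
dense head, Adam, and weighted BCE on logits, with full backpropagation.
Backprop can stop early below the deepest trainable layer (frozen phases
cost less) and can capture the gradient at any named layer output, which is
exactly what Grad-CAM needs. Correctness is pinned by finite-difference
gradient checks on a float64 model (relative error ≲ 1e-6).

The desk-scale backbone is four blocks of two 3×3 conv + ReLU layers
followed by 2×2 max pooling, widths 8/16/32/64, input 64×64. These widths
keep a full cross-validated run tractable on a single CPU core while
remaining comfortably sufficient for the ring-vs-blob texture contrast of
the synthetic slides; "last two blocks" in phase 2 maps to blocks 3–4.
Larger pretrained backbones can be plugged in through the same
`BackboneSpec` contract.

### Training-schedule presets

`TrainingSchedule()` keeps the fine-tuning constants appropriate to a
pretrained backbone: rates 1e-4 / 1e-5, batch 64, last two blocks unfrozen.
Those rates assume useful pretrained features; a randomly initialised small
CNN cannot learn anything in 1 + 10 epochs at 1e-5.
`TrainingSchedule.from_scratch()` therefore keeps the two-phase structure
(head warm-up, fine-tune at a lower rate, best-epoch restore) but uses
rates 1e-2 / 3e-3, batch 16 (more optimiser steps on small tile sets), and
unfreezes every block in phase 2 — freezing random, untrained blocks would
serve no purpose. The from-scratch preset is the default of `run_cv` and
the CLI; both presets were fixed from training-dynamics exploration on
separable ring/blob tile sets.

## Synthetic study conditions

Real immunostain WSIs cannot be redistributed, so `synthetic_data` draws
schematic brown-on-blue pseudo-slides. Background is hematoxylin-like
RGB (0.75, 0.75, 0.85); the chromogen is DAB-like RGB (0.55, 0.35, 0.15);
per-pixel Gaussian noise (SD 0.02) is added and everything is clipped to
[0, 1]. Object counts are Poisson with the stated densities per 10⁴ px²:

* **capillary rings** (microcirculation pattern): annuli, outer radius
  6–15 px, rim 2–3 px, brown rim over a lumen-coloured interior; a
  `focality` < 1 confines them to a random circular sub-region covering
  that fraction of the slide (the focal, GBP1-like regime);
* **interstitial blobs**: filled discs, radius 3–6 px;
* **tubular profiles**: larger annuli, radius 15–30 px, rim 4–6 px, with a
  weaker cytoplasmic fill.

Class defaults: ABMR slides use ring density 3.0 (≈ 70 % of 64-px tiles
carry at least one ring, so weak tile labels stay informative) with light
blob/tubule contamination (0.3 each); OTHER slides use blob density 2.0 and
tubule density 1.0 with no rings. The demonstration cohort is 24 slides —
8 ABMR / 16 OTHER, the ≈ 1:2 imbalance of the motivating 17-vs-37 cohort —
of 256×256 px (4×4 tiles of 64 px). Cohort generation also samples C4d
status and Banff ordinal scores with microvascular inflammation (g, ptc)
concentrated in the ABMR class. All geometric constants are artifact
choices: the source material describes the staining patterns qualitatively
only, and none of these defaults is a claim about tissue morphology.

The *null* condition draws both classes from the identical (ABMR) parameter
set, removing the class effect while keeping everything else fixed; the
pipeline should then score at chance.

What passing on this generator shows — and what it does not: the synthetic
slides exercise the weak-label training loop, the ordered aggregation, the
grouped stratified validation and the explanation machinery under a known
ground truth, and the effect/null pair demonstrates parameter recovery and
calibration at chance. They do not contain scanner artifacts, stain
variability, tissue texture or ambiguous intermediate patterns, so synthetic
performance says nothing about accuracy on real biopsies.

## Statistics layer

All statistics in `diag_stats` are implemented from their definitions
(scipy/sklearn equivalents serve as independent cross-checks in the tests):

* **Majority rule**: strict per-case majority over non-missing raters;
  ties defer to a designated rater; a tie with that rater missing is
  undefined.
* **Cohen's κ** `(p_o − p_e)/(1 − p_e)` with marginal-product expected
  agreement; **Light's κ** is the mean of all pairwise Cohen κs, with
  undefined pairs excluded (warning). Missing calls are deleted pairwise.
* **Fisher exact (2×2, two-sided)**: sum of hypergeometric point
  probabilities ≤ that of the observed table (relative slack 1e-7). The
  point-probability rule — R's `fisher.test` convention — is used because
  it reproduces all three published marker-vs-C4d p-values (0.24, 0.45,
  0.57) at printed precision; the tail-doubling rule does not.
* **mean (SD) reporting**: sample SD (n−1 divisor) and half-away-from-zero
  integer rounding — the only pair of conventions that reproduces the
  published per-reader summaries exactly.
* **Spearman**: average ranks for ties; two-sided p from the t
  approximation with n−2 df (the mainstream correlation-test default), with
  an exact permutation p available for n ≤ 8.

## Numerical and design choices

* Quantiles interpolate linearly between order statistics (the common
  default of mainstream numerical stacks); SD is the sample SD, defined as
  0 for n = 1.
* Pixel coordinates are 0-based half-open intervals; ROI membership uses
  pixel centers. Partial border tiles are dropped.
* ROC curves keep every threshold (no intermediate dropping) so the
  closest-top-left tie-break is exact; AUC is trapezoidal and equals the
  tie-corrected rank-sum statistic to 1e-12.
* `evaluate_repeated` varies only the forest seed across its 50 iterations;
  the averaged threshold across iterations is reported as-is, inheriting
  its awkward interpretation from the protocol it reproduces.
* Forest hyperparameters other than tree count stay at library defaults.
* Whether the phase-1 epoch competes in best-epoch restoration was an open
  point; it does compete here.
* Degenerate inputs: an ROI smaller than one tile yields an empty tile set
  (not an error); an empty prediction series cannot be aggregated; constant
  scores have no defined operating point; identical constant raters have no
  defined κ.

## Problem sizes used in the shipped checks

The test suite and the acceptance script run the full pipeline at desk
scale: 24-slide cohorts of 256×256 px slides (16 tiles of 64 px each), the
small backbone above, 2 repeats × 3 folds, 50 forest iterations per fold —
sizes chosen so a complete effect + null pair of runs finishes in minutes
on one CPU core while still averaging enough folds to be stable. Unit tests
use 200 + 200 separable pattern tiles for the learnability check (validation
AUC ≥ 0.95).

## Known limitations

* The model-selection set of model 1 doubles as the fold's validation set,
  an optimistic bias accepted for protocol fidelity.
* The synthetic generator's realism limits are listed above; in particular
  tile AUC on weakly labelled synthetic cohorts saturates well below 1 even
  when slide-level separation is perfect, because ring-free tiles of ABMR
  slides carry positive labels.
* Pretrained backbones (and 512-px inputs) are supported by contract but
  not exercised by the shipped tests.
* No calibration of forest probabilities, no attention/top-k aggregators,
  no Grad-CAM++ or guided backprop, no pyramidal slide formats.
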