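# Methods

## Pipeline model

`rectseg` implements a two-stage pipeline for rectum segmentation in
pelvic CT.  Stage 1 is a convolutional sex classifier; stage 2 is a
sex-conditioned U-Net segmenter.  The two stages are *architecturally*
shared (identical encoder design: two 3×3 conv + ReLU pairs per level,
channels doubling per level, 2× max-pooling) but trained independently
with separate weights — the segmenter is trained with the ground-truth
sex as two constant one-hot input channels, and only at inference does
the classifier's prediction flow into the segmenter.  This keeps
segmentation training free of classification errors while still testing
the full predicted-sex path end to end.

Conditioning is input-level channel concatenation: channel 0 is the
z-scored image, channels 1–2 the one-hot sex planes.  Constant input
channels preserve the network's translation covariance up to boundary
effects.  The first-layer weights attached to the sex planes are
**zero-initialized** (the image-channel weights are drawn exactly as in
an unconditioned network): random weights on constant-one channels
inject per-filter bias noise that measurably slows early training,
whereas with zero-init the conditioned network starts functionally
identical to its unconditioned twin and grows into the sex prior only
where it reduces the loss.  Per-layer initialization streams are
spawned independently, so the conditioned and unconditioned segmenters
share their entire initial weight set — the conditioning-benefit
comparison is exactly seed-paired.  The output head is a 1×1 convolution with sigmoid, binarized
at probability 0.5; the loss is binary cross-entropy on the logits for
both stages.  No batch normalization is used; weights are
Kaiming-uniform initialized from a seeded generator, so training is
bit-reproducible for a fixed seed in a fixed BLAS configuration.

The conv-net engine is written in NumPy (im2col convolutions evaluated
by BLAS matmul, stride-2 kernel-2 transposed convolutions, 2^d max
pooling, Adam).  One code path serves 2D and 3D; correctness is pinned
by finite-difference gradient checks in the test suite.

## Training protocol

* Patient-level stratified 80:20 train/test split; 20 % of the training
  pool held out for validation; 5-fold cross-validation over the
  training pool for confidence intervals.  Splits are seeded and
  leakage is asserted programmatically.
* Adam, lr 1e-4 (clinical-scale default), up to 100 epochs, early
  stopping on validation loss with patience 7, best-checkpoint restore.
* Classifier and segmenter share one `TrainConfig`; `sex_aware=False`
  trains an otherwise identical unconditioned segmenter as the baseline
  for the conditioning-benefit comparison.

**Desk scale.**  The shipped experiments run a scaled-down regime
(`desk_scale_config`): 60-subject cohorts on a 96×96×48 grid at 1×1×3 mm,
2D mode on the central axial slice (the in-plane lattice is already
1 mm isotropic), a 3-level U-Net with 8 base channels, lr 1e-3 and at
most 45 epochs.  The larger learning rate and smaller width are the
package's choice for the much smaller network and cohort of this
regime; the clinical-scale defaults remain 1e-4/100.  At this scale the
whole pipeline (cohort → two trained stages → held-out metrics) runs in
a few minutes on one CPU core.

## Phantom cohort

The generator emulates a two-stratum radiotherapy-planning cohort:
males with prostate cancer, females with cervical cancer (sex and
diagnosis are deliberately confounded, as in the emulated cohort
design).  Geometry is analytic and rasterized on the grid, so ground
truth is exact:

* **Soft-tissue pelvis**: elliptic cylinder; lateral half-width
  0.34 × grid extent for males plus `pelvis_width_shift` (default
  12 mm) for females, with ±1.5 mm per-subject jitter.  This is the
  learnable sex cue.
* **Bone**: two ellipsoidal iliac stand-ins whose separation follows
  pelvis width (label 2).
* **Rectum** (label 3): a tube swept along a sinusoidal centerline with
  a disc cross-section in every axial plane, plus a subtle sex-dependent
  lateral offset (±2 mm).  Because the cross-section is an axial disc,
  the rasterized volume is π r² L independent of centerline curvature;
  the outer radius is solved per subject from a volume drawn from a
  sex-specific normal truncated at ±3 sd — male 98.4 ± 14.3 cm³, female
  86.3 ± 13.2 cm³.  Only mean ± sd (and a matching median) are known for
  the emulated cohort, so normality is an assumption; under the
  symmetric truncated normal the median equals the mean, which is what
  the calibration tests check.  Measured rasterization bias is
  < 0.05 cm³.  Inside the tube sits an air lumen at
  `r_outer − wall_thickness`, with wall thickness sex-dependent
  (male 4.5 mm, female 3.0 mm, per-subject sd 0.3 mm).
* **Intensities**: per-class HU means (air −1000, soft tissue 40, bone
  700) plus Gaussian noise (sd 15 HU, a typical clinical CT noise
  level).  The rectal wall carries the *same* mean HU as surrounding
  soft tissue — as in clinical CT, where the outer rectal contour has
  essentially no intensity contrast against perirectal tissue.  Only
  the air lumen is intensity-visible, so recovering the contoured outer
  boundary requires combining the lumen with a wall-thickness prior;
  the sex-dependent wall thickness is exactly the anatomical prior that
  sex conditioning supplies, making the conditioning benefit a real,
  recoverable signal rather than a redundant shortcut.

Subject seeds derive from the master seed via `SeedSequence` spawning;
cohorts are byte-reproducible.  If a sampled organ leaves the pelvis,
the subject is re-drawn (bounded retries); with the default geometry the
retry rate is ~0.

**What the phantom does *not* model**: bladder/bowel filling, gas
pockets, HU texture, partial-volume effects, scanner artifacts, true
inter-patient anatomical diversity.  Passing the end-to-end tests shows
the pipeline machinery (conditioning, training, inference, metrics) is
correct and that the conditioning signal is recoverable — it does not
certify clinical-grade accuracy on real CT.

## Metrics

Overlap metrics (smoothed Dice with ε = 1, precision, recall with the
reference mask as denominator-defining argument) are computed on the
native lattice; surface metrics (exact symmetric Hausdorff — the
supremum, not HD95 — and average symmetric surface distance) are
computed between surface-voxel-center point sets in world millimetres
and **refuse anisotropic lattices**: volumes are resampled to isotropic
1 mm (nearest-neighbour for masks, trilinear for images) first.
Surface voxels are mask voxels with ≥ 1 background 6-neighbour (grid
border counts as background); the KD-tree evaluation is tested to agree
with an all-pairs brute-force oracle to 1e-9 mm.  Classification
metrics use male as the positive class; AUC is the trapezoidal area
under the empirical ROC.

## Statistics

* Normality gate: Shapiro–Wilk at α = 0.05; constant samples are
  non-normal by convention.
* Paired: Wilcoxon signed-rank (zeros dropped; exact null for n ≤ 25,
  continuity-corrected normal approximation above) or paired t;
  unpaired: Mann–Whitney U or Welch's t.  Welch is used for *all*
  normal-branch unpaired comparisons rather than gating on a variance
  test — a deliberately conservative simplification.
* Effect sizes: rank-biserial (r = (W⁺−W⁻)/(W⁺+W⁻) paired,
  r = 2U/(n₁n₂)−1 unpaired) on rank branches; Cohen's d with sd of
  differences (paired) or √((s₁²+s₂²)/2) (unpaired) on t branches.
* Families of comparisons pass through Benjamini–Hochberg step-up
  adjustment before reporting.
* Fold CIs are t-intervals over k-fold means: mean ± t_{k−1,1−α/2}·sd/√k.
* Bland–Altman: bias = mean(pred−ref), LoA = bias ± 1.96 sd (n−1).
* Fleiss' kappa on items × raters Likert tables; an all-one-category
  table saturates chance agreement (P̄ₑ = 1) and is flagged undefined
  rather than reported.  Real clinical ratings are not available, so a
  simulator produces tables with configurable marginals and
  rater-agreement strength for testing and reporting structure.

## Numerical and design choices

* 0-based voxel indexing, RAS world frame,
  world = origin + index · spacing; spacing is explicit everywhere and
  anisotropy is never silently dropped.
* Label scheme 0/1/2/3 (background, soft tissue, bone, rectum); mask
  extraction is exactly "label == 3" and binarization is always explicit.
* Augmentation: in-plane rotation ±15°, axis flips, isotropic scaling
  0.9–1.1, global intensity shift (sd 10 HU — magnitude is a package
  choice); images interpolate trilinearly with air fill, masks
  nearest-neighbour with zero fill.  Rotation is axial-only by default,
  matching patient-positioning variability.
* Classifier tie at p = 0.5 resolves to male (documented, tested).
* A classifier probability map threshold of 0.5 binarizes the segmenter
  output; configurable.
* The desk-scale conditioning-benefit comparison evaluates both
  segmenters with ground-truth sex channels, isolating the effect of
  conditioning from classification error (at desk scale the classifier
  is at or near 100 % accuracy anyway).

## Known limitations

* The NumPy engine targets desk-scale problems; clinical-resolution 3D
  training (256³, 100 epochs) is out of its intended range.
* 2D desk-scale mode evaluates mid-pelvis slices; volumetric 3D metrics
  are exercised at small scale only.
* The phantom's sex cue is geometric and strong; real sex classification
  from CT relies on subtler features, so phantom classification scores
  should not be read as clinical estimates.
* Wilcoxon exact p-values assume no ties; ties fall back to the normal
  approximation inside scipy.
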