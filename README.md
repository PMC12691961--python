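# rectseg

Sex-aware two-stage deep-learning pipeline for automated **rectum
segmentation in pelvic CT**, with a synthetic pelvic phantom cohort,
radiotherapy-grade evaluation metrics and clinical-validation statistics.

## The problem

The rectum is a critical organ at risk in radiotherapy planning for
prostate and cervical cancer.  Manual contouring is slow and shows
inter-observer variability, and rectal anatomy differs systematically
between male and female pelvises.  `rectseg` implements a pipeline that
exploits that difference explicitly:

1. **Stage 1 — sex classification.**  A convolutional encoder predicts the
   patient's biological sex from the CT image alone:
   `p(male) = σ(f_enc(x))`.
2. **Stage 2 — sex-conditioned segmentation.**  A U-Net (symmetric
   encoder–decoder with skip connections, 3×3 convolutions + ReLU, 2×2
   max-pooling, transposed-convolution upsampling, sigmoid output) receives
   the image **plus two constant one-hot sex channels** and produces a
   per-voxel rectum probability map.  Training uses the ground-truth sex;
   at inference the stage-1 prediction conditions stage 2.

Both stages train with Adam and binary cross-entropy, patient-level
stratified 80:20 splits (20 % of training held out for validation), early
stopping (patience 7) and 5-fold cross-validation.  The conv-net engine
(ND convolutions with im2col, pooling, transposed convolutions, Adam,
backprop) is implemented in NumPy and runs identically in 2D and 3D.

Evaluation follows the standard organ-at-risk metric set, with ε = 1
Dice smoothing:

- `DSC = (2|X ∩ Y| + ε) / (|X| + |Y| + ε)`
- `ASD = [Σ_{x∈S_X} d(x, S_Y) + Σ_{y∈S_Y} d(y, S_X)] / (|S_X| + |S_Y|)`
- `HD  = max{ sup_{x∈S_X} d(x, S_Y), sup_{y∈S_Y} d(y, S_X) }`

where `S_X, S_Y` are surface voxel sets in world millimetres; surface
metrics require (and the pipeline performs) resampling to isotropic
1×1×1 mm voxels so that 3 mm CT slice spacing cannot inflate distances.
The statistics layer provides Shapiro–Wilk-gated test selection
(Wilcoxon signed-rank / paired t; Mann–Whitney U / Welch t), rank-biserial
and Cohen's d effect sizes, Benjamini–Hochberg FDR correction, fold-based
t-intervals, Bland–Altman limits of agreement and Fleiss' kappa for
3-point Likert rating tables.

Because clinical CT cohorts cannot be redistributed, the package ships a
**phantom generator**: a two-stratum cohort (male/prostate,
female/cervical) of CT-like volumes with sex-dependent pelvic geometry
and an exactly known rectum label (label 3), whose per-stratum rectal
volume distributions are calibrated to 98.4 ± 14.3 cm³ (male) and
86.3 ± 13.2 cm³ (female).

## Worked example

```python
from rectseg.phantom import PhantomConfig, generate_cohort
from rectseg.trainer import TwoStagePipeline, desk_scale_config

records = generate_cohort(PhantomConfig(seed=11), 30, 30, "cohort")
pipeline = TwoStagePipeline(records, desk_scale_config(seed=11))
results = pipeline.fit()
print(results.summary())
```

prints

```
Two-stage sex-aware rectum segmentation — held-out test results
================================================================
subjects: 12 test / 48 train (sex-aware=True)

Sex classification (male = positive class):
  accuracy             1.0000
  sensitivity_male     1.0000
  specificity_female   1.0000
  ppv                  1.0000
  npv                  1.0000
  f1                   1.0000
  auc                  1.0000

Segmentation (per-cohort mean):
  cervical  DSC=0.984  HD=3.38 mm  ASD=0.39 mm  (n=6)
  prostate  DSC=0.984  HD=1.07 mm  ASD=0.30 mm  (n=6)
```

i.e. on a 60-phantom cohort the sex classifier separates the sexes
perfectly from the pelvic geometry, and the sex-conditioned segmenter
recovers the rectum with mean Dice ≈ 0.98 and sub-millimetre average
surface distance on the held-out subjects.

The same flow is available from the shell:

```sh
rectseg simulate --n-male 30 --n-female 30 --out cohort --seed 11
rectseg train --manifest cohort/manifest.csv --out runs/demo --seed 11
rectseg run-all --n-male 30 --n-female 30 --out runs/full --seed 11
```

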