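# liverseg

Automatic liver volumetry for abdominal MR: three orthogonal 2D
encoder–decoder networks fused by a per-voxel majority vote, together with
the volumetric quality metrics and multi-observer agreement statistics
needed to validate such a method — all exercisable end to end on a
synthetic abdominal phantom generator, so every stage is testable without
clinical data.

Total liver volume drives the planning of liver surgery and
radioembolization (SIRT), and manual contouring is slow and
observer-dependent. The toolkit is aimed at researchers building or
validating automatic liver segmentation pipelines and at anyone who needs
the statistics of a multi-observer volumetry study.

## Method

**Segmentation.** One 2D U-net-like model per slicing plane (axial,
coronal, sagittal). Each model works on four resolution levels with 3×3
valid-mode convolutions, 2×2 stride-2 (transposed) convolutions for
rescaling, batch normalization and ReLU after every convolution, long
encoder→decoder concatenation skips, short residual skips within blocks,
and dropout in the upscaling path. The default block structure gives a
receptive field of 93 × 93 pixels, so at 2 mm voxels each output pixel
sees ≈ 18.6 cm of anatomical context; being valid-mode, an input patch of
side *N* yields an output of side *N* − 92. Hard per-orientation
predictions are fused per voxel by majority vote:
fused(x) = 1 ⇔ at least 2 of the 3 models predict 1.

**Preprocessing and training.** Volumes are resampled to 2 mm isotropic
voxels and their 2nd–98th intensity percentiles mapped linearly to
[0, 1]. Models train on 228×228 label patches (inputs reflect-padded by
the context radius), mini-batch 16, soft Dice loss
L = 1 − (2Σpg + ε)/(Σp + Σg + ε), Adam at 10⁻⁴, with rotations
α ~ N(0°, 10°) and intensity shifts x ~ N(0, 0.1) as augmentation.
Validation Jaccard is computed on full held-out volumes every 500
iterations; training stops after 20 validations without improvement and
the best checkpoint is kept.

**Evaluation.** Against a reference mask Y, a test mask X is scored by

- DICE(X,Y) = 2|X∩Y| / (|X|+|Y|)
- RVE(X,Y) = |V_X − V_Y| / V_Y · 100 %
- MSD(X,Y) = (Σ_{x∈X} min_y d(x,y) + Σ_{y∈Y} min_x d(x,y)) / (|X|+|Y|)
- HD(X,Y) = max{ sup_x inf_y d(x,y), sup_y inf_x d(x,y) }
- CS = n_c / n_t · 100 % (slices corrected / slices occupied)

with surfaces taken as boundary-voxel centers and d(·,·) the Euclidean
distance in mm honoring anisotropic spacing (exact distance transform,
verified against a brute-force all-pairs oracle).

**Agreement.** Per-case inter-observer variability is the mean absolute
pairwise difference of the observers' RVE values; the cohort is summarized
by its mean ± sample SD. Absolute agreement of raw volumes uses the
two-way random-effects single-measure intraclass correlation ICC(2,1)
with its Shrout–Fleiss 95% CI, and paired comparisons use the Wilcoxon
signed-rank test (exact null for n ≤ 25, two-sided, α = 0.01).

The CNN stack — valid-mode convolutions, transposed convolutions, batch
norm, dropout, reverse-mode gradients and Adam — is implemented directly
on numpy and gradient-checked against finite differences in the test
suite.

## Worked example

```python
from liverseg import (PhantomConfig, ObserverProfile, generate_phantom,
                      simulate_observer_mask, evaluate_case)

image, reference = generate_phantom(PhantomConfig(seed=7))
observer = simulate_observer_mask(reference, ObserverProfile(volume_bias_pct=4.0,
                                                             boundary_noise_mm=1.0,
                                                             seed=7))
report = evaluate_case(observer, reference)
print(f"reference volume: {reference.volume_ml:.1f} ml")
print(f"observer volume:  {observer.volume_ml:.1f} ml")
print(f"DICE {report.dice:.3f}  RVE {report.rve_pct:.2f}%  "
      f"MSD {report.msd_mm:.2f} mm  HD {report.hd_mm:.2f} mm")
```

prints

```
reference volume: 1500.0 ml
observer volume:  1568.1 ml
DICE 0.977  RVE 4.54%  MSD 1.19 mm  HD 3.46 mm
```

The phantom's liver was calibrated to 1500 ml; the simulated observer was
configured to over-segment by ≈ 4% with 1 mm correlated boundary noise,
and the measured RVE of 4.54% with sub-voxel MSD reflects exactly that.

The packaged 21-case, 5-observer RVE table ships with the library:

```bash
liverseg agreement --table src/liverseg/data/interobserver_rve.csv \
    --kind rve --observers Rad,Res1,Res2
# mean per-case variability 2.75% (SD 1.41%)
```

The CLI also exposes `phantom`, `train`, `predict` and `evaluate`
subcommands; every run writes a resolved-config snapshot and derives all
randomness from `--seed`.

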