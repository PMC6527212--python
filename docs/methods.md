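# Methods

This note documents the models, numerical choices and known limitations
of `liverseg`, in the spirit of a methods appendix.

## Segmentation model

Each of the three orientation networks is a valid-mode 2D U-net variant:
four resolution levels, 3×3 convolutions, 2×2 stride-2 convolutions for
downscaling and 2×2 stride-2 transposed convolutions for upscaling, batch
normalization and ReLU after every convolution, long concatenation skips
from encoder to decoder (center-cropped to the decoder's valid extent),
short residual skips within every convolution block (1×1-projected when
channel counts change, added before the block's final ReLU), and dropout
(default rate 0.2) in the upscaling path only. The output head is a 1×1
convolution to two channels with a softmax; hard predictions take the
foreground channel at probability ≥ 0.5, which for two channels is the
argmax. Feature counts default to 32 at the finest level, doubling per
level (32/64/128/256); these are conventional for this depth and
configurable.

### Receptive field

The block structure is encoder (2, 3, 2) convolutions per level, 2 in the
bottleneck, decoder (2, 2, 2). The receptive field is computed by the
context recursion: a 3×3 convolution consumes (k−1)·jump = 2·jump input
pixels, where jump is the input-pixel stride of the current grid; the 2×2
stride-2 rescalers have kernel equal to stride, tile the grid exactly and
consume no context, only doubling (halving) the jump. For the default
structure:

RF = 1 + 2·(2 + 2·3 + 4·2) + 8·2·2 + 2·(4·2 + 2·2 + 1·2) = 93.

Equivalently, output size = input − (RF − 1): a 320-pixel input yields a
228-pixel output. Patch-based training therefore pads 228-pixel label
windows by 46 pixels per side with reflection.

Two subtleties are worth recording. First, not every input size passes
through the stride-2 stages; valid sizes recur with period 8 and the
code exposes `next_valid_input` (inference pads to the next valid size
and crops back, which changes nothing because the convolutions are
valid). Second, the *per-output-pixel* influence window of the real
network is position dependent and wider than RF (96 or 104 pixels for the
default structure) because each stride-2 stage ties neighbouring input
pixels into pairs; any such window width is necessarily even. The
perturbation oracle (`perturbation_receptive_field`) therefore measures
the full single-pixel influence matrix of a linearized, bias-free network
(ReLU and batch norm disabled, weight magnitudes, so influence cannot
cancel) and reports the translation-normalized influence span,
`max_j hi_j − min_j lo_j + 1 − (n_out − 1)`, which removes the
one-output-pixel shift per input-pixel shift. This measured quantity
equals the analytic RF (93) and is the number that the padding
arithmetic actually uses; the raw per-pixel window widths are returned
alongside for inspection.

### Numerical stack

No GPU framework is used: convolutions, transposed convolutions, batch
normalization, dropout, softmax, the soft-Dice objective and Adam are
implemented on numpy with reverse-mode automatic differentiation
(`liverseg.nn`). Every primitive's gradient is checked against central
finite differences in the test suite. Arrays are float64; convolutions
are evaluated as nine (kernel-offset) einsum contractions, which is
efficient at the patch sizes used here.

## Training procedure

- **Sampling.** A random case, a random slice along the orientation axis,
  and a random in-slice label window; half of the windows are centered
  inside the liver bounding box (class balance), half uniform over the
  slice. The input window is the label window grown by (RF−1)/2 per
  side; reflection padding covers whatever lies outside the slice. The
  sampler derives its padding from the built model, so label and output
  windows coincide exactly — this alignment is load-bearing and is tested
  by thresholding noiseless phantoms.
- **Augmentation.** In-plane rotation α ~ N(0°, 10°) (linear for images,
  nearest for labels, so labels stay binary) and a uniform intensity
  shift x ~ N(0, 0.1) added after normalization without re-clipping.
- **Objective.** Batch-aggregated soft Dice,
  1 − (2Σpg + ε)/(Σp + Σg + ε), ε = 10⁻⁵, non-squared denominators; the
  ε convention scores an all-empty batch as perfect.
- **Optimization.** Adam, learning rate 10⁻⁴, mini-batch 16 (defaults).
  Model quality is the mean *full-volume* Jaccard over held-out
  validation cases (a seeded case-level split, fraction 0.2), evaluated
  every 500 iterations; training stops after 20 validations without a new
  best, and the best checkpoint is returned. Slice-wise validation would
  also be defensible; full-volume was chosen because the clinical
  quantity of interest (volume) is global.

Tests and the smoke pipeline run a scaled-down configuration — two
levels, 8 base features (RF 17), 24-pixel patches, batch 8, phantoms of
48×48×32 voxels at 2 mm with ≈ 300 ml livers — chosen so that the numpy
trainer converges on separable phantoms in under a thousand iterations.
On that task it reaches validation Jaccard ≥ 0.99, demonstrating correct
patch/label alignment and a functioning optimization loop; it says
nothing about clinical-image performance.

## Phantom generator

The generator emulates a late-phase contrast-enhanced abdominal volume:

- **Liver shape**: the union of 2–4 overlapping ellipsoids (smooth bumps
  combined by a max), deformed by a Gaussian-smoothed random field —
  deliberately non-convex so that surface metrics are exercised beyond
  symmetric shapes. The iso-level of the shape field is calibrated by
  bisection (on the largest 6-connected, hole-filled component) so the
  mask volume hits the configured target, 1500 ml by default, typically
  to well under 1%.
- **Intensities**: background 0.2, liver 0.7, lesions 0.4, confounders
  0.65 (arbitrary units, pre-normalization), Gaussian noise added last.
  Lesions are spheres inside the liver, a configurable fraction touching
  the boundary; the mask keeps them as foreground, as clinical liver
  volumes include tumours. Confounders are bright structures disjoint
  from the liver that reproduce the "similar adjacent organ" failure
  mode.
- **Observers**: the reference's signed distance field (in mm, smoothed
  by one voxel so its level sets move sub-voxel-continuously) is shifted
  by a uniform offset — found by bisection so the noiseless volume equals
  (1 + bias/100)·V_ref — and displaced by zero-mean Gaussian-smoothed
  noise scaled to `boundary_noise_mm`. This produces spatially correlated
  boundary errors rather than salt-and-pepper voxels. A zero-bias,
  zero-noise profile returns the reference bit-identically.

What the phantom does **not** model: MR bias fields, pharmacokinetics,
multi-organ anatomy, partial-volume texture, realistic lesion appearance.
Passing tests on phantoms therefore demonstrate the correctness of the
pipeline's mechanics and statistics, not clinical segmentation quality.

A note on parameter recovery: the mean absolute pairwise difference of
*signed* relative volume errors recovers a configured ±b% observer-bias
gap (2b) in the small-noise regime; at larger boundary noise the folded
absolute value and the curvature of the volume response add an O(σ²)
upward bias. The recovery experiments therefore use 0.5 mm boundary
noise, where the linear prediction holds to within Monte-Carlo error.
Published-style observer tables carry absolute RVE values (as in the
packaged table, whose footnote arithmetic confirms pairwise differences
of absolute values); cohort evaluation records the signed variant
alongside for recovery studies.

## Metrics

Surfaces are the world-space centers of foreground voxels with at least
one 6-connected background (or out-of-grid) neighbour. MSD and HD use
the exact Euclidean distance transform with per-axis mm sampling and are
tested to equal the O(|X||Y|) all-pairs oracle to machine precision,
including anisotropic spacing. The symmetric MSD denominator is
|X| + |Y| (the common 1/(2N) form assumes equal surface sizes and is
recovered when |X| = |Y|). RVE is computed from each mask's own voxel
volume, so volumetry across different grids needs no resampling; it is
the only asymmetric metric. CS counts slices along a configurable axis
(default axial, where contouring corrections happen) where the corrected
and automatic masks differ, over slices the automatic mask occupies.
Whether metrics are computed at original or working (2 mm) resolution is
the caller's choice; evaluation defaults to the masks as given, and
`segment` returns the fused mask in both geometries.

## Agreement statistics

ICC(2,1) is computed from the two-way ANOVA mean squares
(MS_R − MS_E) / (MS_R + (k−1)MS_E + k(MS_C − MS_E)/n) with the
Shrout–Fleiss/McGraw–Wong F-based 95% interval (Satterthwaite df for the
lower-bound denominator); it is restricted to raw volumes by the
`ObserverTable.value_kind` contract, since absolute agreement of an error
quantity is not meaningful. The test suite checks the point estimate
against an independently coded ANOVA oracle to 10 significant digits and
against pingouin's ICC(A,1). A degenerate (all-equal) table returns ICC 1
with a warning. The Wilcoxon signed-rank test drops zero differences,
uses midranks for ties, and computes the exact two-sided null for n ≤ 25
by convolving the (doubled) rank distribution — so a constant shift of
21 pairs attains the minimal p = 2/2²¹ ≈ 9.5·10⁻⁷ — falling back to the
tie-corrected normal approximation with continuity correction for larger
n. The cohort SD of per-case variability is the sample SD (n − 1).

## Reproducibility

All randomness flows through explicit integer seeds into numpy PCG64
generators: phantom and observer seeds are recorded in the cohort
manifest (rebuilds are bit-identical), model initialization, patch
sampling, augmentation and dropout derive from the training seed, and
inference is deterministic. CSV reports print percent metrics with 2
decimals; JSON keeps full precision.

## Known limitations

- Pretrained clinical weights are not shipped; published clinical-cohort
  metric values cannot be recomputed without the original DCE-MRI data.
- The numpy trainer is single-threaded and meant for the default
  architecture only at patch scale; full-scale training runs are hours,
  not minutes.
- No shape prior or postprocessing is applied by default (an optional
  largest-component flag exists), so implausible components are possible
  on hard inputs.
- NIfTI axis handling supports orthogonal (signed-permutation)
  orientations; oblique acquisitions must be resampled upstream.
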