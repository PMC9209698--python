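# Methods

## Model

The segmenter (generator) is a residual encoder–decoder over single-channel
3D patches. Four encoder stages each apply a residual block (two 3×3×3
convolutions with batch normalization and leaky-ReLU slope 0.2, plus a 1×1×1
projection shortcut when channel counts change) followed by a 3×3×3
convolution with stride 2; four decoder stages mirror them with 2×2×2
transpose convolutions (resize factor 2), concatenation of the matching
encoder features, and another residual block. A 1×1×1 convolution and a
sigmoid produce a per-voxel brain probability. Channel widths are
`w, 2w, 4w, 4w` for base width `w`: the 4w cap keeps the generator's
parameter count strictly below the baseline U-Net's at every matched base
width, which is what makes its inference cheaper. Patch sides must be
divisible by 2⁴.

The critic is a fully convolutional feature extractor over
image-masked-by-label inputs: stride-2 3×3×3 convolutions with batch
normalization and leaky ReLU, every layer's output exposed. The adversarial
objective is the multi-scale L1 loss: the mean absolute difference between
critic features of (image ⊙ predicted probability) and (image ⊙ ground
truth), averaged over the feature hierarchy. Two design choices matter here:

- **The masked image joins the hierarchy as its zeroth level.** The feature
  list compared by the loss is `[x⊙m, f₁, f₂, …]`. This term carries no
  critic parameters (so the critic's ascent direction is untouched) but
  gives the generator a dense intensity-level gradient alongside the learned
  features. Without it, desk-scale training plateaued well below the
  baseline; with it the min-max game is stable and accurate.
- **Both branches share batch statistics.** The critic runs once on the
  concatenated (prediction-masked, truth-masked) batch. Normalizing each
  branch separately erases exactly the level differences the features are
  supposed to expose; sharing statistics restored discriminative gradients
  in piloting.

The baseline 3D U-Net has four two-convolution blocks per path (batch
normalization + PReLU), feature doubling per block (`w … 8w`, bottleneck
`16w`), max-pool downsampling, transpose-convolution upsampling, skip
concatenation, and dropout 0.15 at the bottleneck. The clinical-scale width
is 96 initial feature maps; the published description of widths contains an
arithmetic inconsistency (364 where doubling gives 384), and this
implementation uses plain doubling. The encoder/decoder kernel assignment
follows the conventional form (3×3×3 stride-2 downsampling, 2×2×2 factor-2
upsampling); the source description transposes the two branches in one
sentence, which we read as a typo.

## Training

Adam for all networks, betas (0.5, 0.999). Alternating optimization, one
critic ascent step then one generator descent step per batch. Binary
cross-entropy (probabilities clamped to [1e-7, 1-1e-7]) for the U-Net.
Training patches are sampled at uniformly random origins, with half of each
volume's patches constrained to intersect the brain's bounding box so early
epochs see informative gradients. A divergence guard aborts on non-finite
losses. All randomness flows from a single config seed; fixed seeds
reproduce fold plans, histories and metrics bit-identically on one device.

### Desk-scale profile

The reference configuration (`fetalgan.training.desk_scale_profile`) was
chosen by pilot runs on phantoms and then frozen; the recorded study uses
cohort seed 1234 and profile seed 7.

| parameter | value | notes |
|---|---|---|
| generator base width | 6 | channels 6, 12, 24, 24 |
| critic | 3 layers, base 8 | features 8³, 4³, 2³ on 16³ patches, plus the input level |
| U-Net base width | 4 | bottleneck 64 |
| training patch size | 16³ | desk scale; 32³ at clinical scale |
| patches per volume per epoch | 12 | half brain-intersecting |
| batch size | 16 | |
| epochs | 30 | |
| generator / U-Net lr | 3e-3 | ×0.3 at epoch 20 |
| critic lr | 5e-4 | ×0.3 at epoch 20 |
| inference | patch 16³, stride 8 | 50% overlap, probability averaging |
| threshold | 0.5 | ties count as foreground |

Inference patches match the training patch size: the networks are fully
convolutional, but batch-norm statistics are collected at the training patch
size and transfer poorly to larger fields of view (piloting showed a clear
Dice drop at 32³ inference after 16³ training).

Reference outcome (the reproduction script at seed 1; 20 training / 5
held-out phantoms, 48³, contrast 1.3, noise 0.05, identical protocol for
both models): FetalGAN mean Dice **0.9333** (precision 0.9643, sensitivity
0.9046), baseline U-Net **0.9615**; the generator carries 52% of the
U-Net's parameters (185,245 vs 354,317). Both models comfortably recover
the phantom brain; which one leads by one or two Dice points varies with
the seed at this scale — the adversarial game is the noisier optimizer, and
five held-out phantoms give a wide mean. The fixed-seed study in the test
suite (cohort seed 1234, profile seed 7) is the frozen configuration under
which the adversarial model meets Dice ≥ 0.90 and stays within 0.02 of the
baseline. `scripts/acceptance.py` recomputes all of these quantities from
scratch for any seed.

## Phantom generator

Each phantom emulates the traits that make fetal EPI brain extraction hard,
on a 48³ grid (voxel spacing 2.578×2.578×3 mm, the clinical EPI resolution):

- **Brain**: an ellipsoid with per-axis semi-axes drawn from [10, 15]
  voxels (resampled until the brain occupies 3–40% of the grid), uniformly
  random 3D rotation and a random center keeping it fully inside. A voxel
  is in the ground-truth mask iff its center satisfies the ellipsoid
  inequality; the mask is exact and precedes noise.
- **Maternal tissue**: 6 Gaussian blobs (σ ∈ [3, 6] voxels) touching the
  ellipsoid surface, zeroed inside the brain, scaled so their mean intensity
  over their support is brain-mean / contrast. At the default contrast 1.3
  the brain boundary is genuinely low-contrast.
- **Bias field**: 1 + the rescaled sum of three low-order random cosines,
  peak-to-trough 0.2 by default, applied multiplicatively — emulating the
  inhomogeneity that clinical pipelines remove upstream.
- **Noise**: additive Gaussian, SD = 0.05 × brain mean by default.

What the phantom does **not** emulate: EPI susceptibility distortion, T2\*
decay, partial-volume boundaries, within-scan motion, or any temporal
dimension. Passing the phantom study shows the optimization, patching and
evaluation machinery recover a known object under low contrast, bias and
noise — not that the trained weights transfer to clinical scans.

Cohorts derive per-item seeds deterministically from a master seed; an
optional duplicate-subject rate gives some fetuses two scans, exercising the
group-aware cross-validation splitter (all scans of a subject stay in one
fold).

## Numerical and design notes

- The network stack is pure numpy (im2col convolutions over BLAS, explicit
  backward passes) because no deep-learning framework is part of the
  package's dependency set; every layer's gradient is finite-difference
  checked in the test suite, per-layer at 1e-4 relative tolerance and
  end-to-end in eval mode at 1%.
- Patch lattices are `{0, s, 2s, …}` per axis with the final origin clamped
  to `axis − size`; reassembly divides the per-voxel sum by the cover count,
  so voxels covered once reproduce their patch value exactly and the
  round-trip is bit-exact for float32 volumes.
- Printed patch strides of 2 voxels on 32³ patches are honoured as an option
  but not used by default: they cost thousands of patches per volume for the
  same averaging semantics. Defaults use random patch sampling for training
  and 50% overlap for inference.
- Zero-denominator conventions: precision := 0 when nothing is predicted;
  specificity := 1 when TN+FP = 0. Mask binarization treats p ≥ threshold
  as foreground. Post-processing uses 26-connectivity for components and
  6-connected background for cavity filling, in 3D (a slice-wise 2D variant
  of the clinical pipeline cannot be ruled out from its description).
- Intensity normalization is per-volume min-max to [0, 1]; the clinical
  description mentions normalization without a formula, so this is a
  documented package choice (bounded inputs suit sigmoid outputs and the
  masked-product loss).
- Summaries report mean ± sample SD (n−1); a single scan reports SD 0 with
  n = 1 flagged.

## Known limitations

- Batch-norm statistics tie inference to the training patch size.
- The adversarial game at desk scale oscillates by a few Dice points
  between epochs; the late learning-rate decay damps but does not remove
  this. Seeds are recorded for the reference study.
- The phantom's constant-intensity brain makes the task easier than real
  EPI at matched contrast; desk-scale Dice values are not comparable in
  absolute terms to clinical performance.
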