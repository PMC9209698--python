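# fetalgan

Adversarial 3D patch-based **fetal brain extraction** from resting-state fMRI
EPI volumes, with a 3D U-Net baseline, a five-metric evaluation suite, and a
synthetic phantom generator that makes the whole pipeline trainable and
testable without clinical data.

## The problem

Separating brain from non-brain voxels is the gateway step of fetal rs-fMRI
preprocessing. Standard skull-stripping tools built for adult heads fail on
fetal EPI: the brain is surrounded by maternal tissue, sits at an arbitrary
orientation, and its boundary is low-contrast. In practice the mask for each
scan's reference volume is drawn by hand — slow and operator-dependent.

`fetalgan` implements a SegAN-style adversarial segmenter for this task. Two
networks play a min-max game over a multi-scale L1 feature loss:

```
min_G max_D  L(θ_G, θ_D) = (1/N) Σ_n  l_mae( f_D(x_n ⊙ G(x_n)),  f_D(x_n ⊙ y_n) )
```

where `x` is the EPI patch, `y` the ground-truth mask, `G(x)` the generator's
per-voxel brain probability map, `f_D` the hierarchy of critic feature maps
(the masked image itself is included as the zeroth level), and `l_mae` the
mean absolute difference averaged over the hierarchy. The critic ascends `L`
so its features discriminate prediction-masked from truth-masked images at
every scale; the generator descends `L` so its masks become indistinguishable
from manual ones. The baseline 3D U-Net is trained on the same patches with
plain binary cross-entropy.

Volumes are segmented patch-wise: overlapping fixed-size patches are pushed
through the trained network and the per-patch probability maps are averaged
voxel-wise before thresholding. Post-processing keeps the largest
26-connected component and fills internal cavities. Predictions are scored
with Dice, Jaccard, precision, sensitivity and specificity.

The generator's channel widths are capped at 4x its base width, so at any
matched base width it has strictly fewer trainable parameters than the
U-Net — the reason per-volume inference is cheaper.

## Worked example

A two-minute run on small phantoms (the full desk-scale study below uses 48³
phantoms and the default 30-epoch protocol):

```python
import fetalgan as fg

# synthetic fetal-EPI phantoms: bright ellipsoidal brain, maternal-tissue
# blobs at contrast 1.3, bias field, 5% noise
cfg_ph = fg.PhantomConfig(grid_shape=(32, 32, 32), brain_semiaxes_range=(7.0, 10.0),
                          contrast=1.3, noise_sigma=0.05)
cohort = fg.generate_cohort(cfg_ph, 12, seed=11)
train, test = cohort.subset(range(10)), cohort.items[10:]

cfg = fg.TrainConfig(epochs=20, patches_per_volume=12, batch_size=16,
                     patch_size=16, infer_stride=8, lr_decay_epoch=14, seed=3)
gen, history = fg.train_segan(train, fg.GeneratorSpec(base_channels=4, seed=1),
                              fg.CriticSpec(base_channels=8, seed=2), cfg)

for vol, mask, sid in test:
    prob = fg.predict_volume(gen, fg.normalize_intensity(vol), cfg.patch_spec)
    pred = fg.postprocess(fg.binarize(prob, 0.5))
    m = fg.compute_metrics(pred, mask)
    print(f"{vol.id}: dice={m.dice:.3f} precision={m.precision:.3f} "
          f"sensitivity={m.sensitivity:.3f}")
```

```
sub-0010_scan-010: dice=0.881 precision=0.849 sensitivity=0.916
sub-0011_scan-011: dice=0.846 precision=0.813 sensitivity=0.883
```

Each line scores one held-out phantom: Dice is the overlap between the
predicted and true brain masks, precision the fraction of predicted brain
voxels that are truly brain, sensitivity the fraction of true brain voxels
recovered. Under the full desk-scale protocol (20 training phantoms at 48³,
30 epochs) held-out Dice rises above 0.9 — see the next section.

The same pipeline is scriptable from the shell:

```bash
fetalgan simulate --n 25 --out data/ --seed 1234 --contrast 1.3
fetalgan train    --data data/ --out ckpt/ --model fetalgan --seed 7
fetalgan predict  --model ckpt/fetalgan.npz --in data/sub-0000_scan-000_epi.nii.gz \
                  --out pred/sub-0000_scan-000_mask.nii.gz --patch-size 16 --stride 8
fetalgan evaluate --pred pred/ --truth data/ --out metrics.csv
fetalgan crossval --data data/ --out cv/        # group-aware 5-fold CV
```

## Scope

The package covers segmentation of a single 3D reference EPI volume per
scan. Upstream fMRI preprocessing (slice-time correction, reorientation,
bias-field correction, motion correction) and scanner-specific acquisition
are out of scope, as are surface-distance metrics and 2D variants.
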