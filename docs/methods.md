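# Methods

This note documents the models and procedures implemented in `ribfrac`, the
assumptions behind them, the defaults and why they hold their values, and
what the synthetic phantom experiments do and do not demonstrate.

## Problem setting

Rib fractures are small, low-contrast lesions on thin curved bones; on chest
CT they occupy a vanishing fraction of the volume and are easily confounded
with normal cortical irregularity. The package detects them by voxel-level
segmentation: a 3D network produces a fracture-probability map over the
bone region, and connected components of the thresholded map become
detection proposals scored by their mean probability. Performance is read
out at the lesion level with FROC analysis.

## Bone-region preprocessing

Input scans are dense HU volumes with per-axis spacing in mm, axis order
(L, W, H), never resampled (clinical slice thickness 1.25–5 mm is accepted
as-is). The extraction pipeline is, in order:

1. **Binarize** at ≥ 180 HU (inclusive — the boundary voxel is kept).
2. **Size-filter**: remove connected components with physical volume
   strictly below 4000 mm³ (voxel count × voxel volume from the spacing).
   Running this *before* dilation matters: dilation would otherwise glue
   debris, table parts and calcifications onto the ribcage, after which the
   largest-component step could not shed them.
3. **Dilate** with a 6-connected unit ball, 3 iterations by default. The
   dilation recovers the peri-cortical soft tissue that matters for reading
   fractures and bridges thin gaps so the cage stays one component. Element
   and iteration count are config-exposed; an optional binary closing
   (`closing: true`) is available for additional hole filling but off by
   default.
4. **Largest component** (26-connectivity by default) — the spine-connected
   ribcage. Ties are broken toward the component whose first voxel in
   row-major scan order comes first, which is deterministic.
5. **Mask**: voxels inside keep their HU, voxels outside become −300 HU.
6. **Window + normalize**: clip to the bone window (level 300, width
   1200 HU) and map linearly to [0, 1] using the *fixed* window bounds
   [−300, 900] as min/max. Fixed bounds make the mapping identical across
   scans and send the −300 HU background fill to exactly 0, which is what
   lets inference recognise tissue-free windows. A mode using the observed
   min/max is available behind a flag.

## Network

`AttentionResUNet3D` is a residual 3D U-Net: four encoder stages (channels
c, 2c, 4c, 8c; base width c = 32 by default, config-exposed) with 2×2×2
max-pooling between them, and three decoder stages that upsample with
kernel-2/stride-2 transpose convolutions. Every stage is a residual block —
two (3×3×3 conv → batch-norm → ReLU) layers plus an additive shortcut,
with a 1×1×1 projection when channel counts change. A 1×1×1 convolution
and sigmoid produce the voxel probabilities. Weights are He-initialised
from a seeded generator; batch norm uses per-batch statistics in training
and running averages (momentum 0.1) at inference.

Two attention mechanisms refine each decoder stage, both multiplicative
with sigmoid gates strictly inside (0, 1) — they preserve shape and sign
and strictly shrink magnitudes:

* **Channel fusion attention** (skip connections). The encoder map F_e and
  the upsampled decoder map F_d are reduced to per-channel means by global
  average pooling; the two length-C statistics are concatenated and a
  single-channel 1D convolution of odd kernel n = 5 slides across the
  length-2C sequence (local cross-channel interaction, no dimensionality
  reduction), followed by a sigmoid. The first C gates rescale F_e
  channel-wise and the last C rescale F_d, letting the two feature
  hierarchies adjust to each other before fusion. One shared convolution
  produces both gate sets by default; since the defining expressions for
  the two gate vectors are identical, sharing is the faithful reading, but
  an unshared two-convolution variant is kept behind
  `shared_channel_conv=false`.
* **Grouped spatial attention** (after fusion). Channels split into G = 4
  contiguous groups; each group is projected to one channel by its own
  1×1×1 convolution, convolved with its own 7×7×7 kernel (padding 3, with
  bias), and passed through a sigmoid to give a per-voxel gate map that
  rescales the whole group. Group weights are independent so each gate map
  can attend to a different semantic sub-feature; G = 1 recovers ungrouped
  spatial attention. G must divide every decoder-stage channel count.

Ablation toggles (`use_channel_attention`, `use_spatial_attention`,
`spatial_groups`) replace either module by the identity, reproducing the
plain residual U-Net backbone and the single-group variant; enabling either
module strictly increases the parameter count.

The exact per-stage channel widths of the original design are not published;
c = 32 with doubling is the conventional choice and is config-exposed.

### Implementation

The network, backpropagation and optimiser are implemented directly in
NumPy/SciPy. Multichannel convolutions are evaluated by shift-and-accumulate
(one (C_out × C_in) matmul per kernel offset over contiguous slabs), large
single-channel kernels (the 7×7×7 gates) by FFT convolution; each layer
implements an explicit backward pass. The whole graph is verified against
central finite differences at float64 in the test suite (worst relative
error ~1e-6 on sampled parameters). Training uses Adam (β₁ = 0.9,
β₂ = 0.999, ε = 1e−8) at learning rate 1e−3 with L2 weight decay 1e−4
folded into the gradient.

## Objective

Total loss = soft Dice + weighted BCE, computed over the batch and reported
separately:

* Dice: 1 − 2Σyp / (Σy + Σp + ε), ε = 1e−5 guarding the all-empty patch
  (the published formula carries no ε; its effect is bounded by ε).
* Weighted BCE: −mean(α·y·log p + (1−y)·log(1−p)) with positive-voxel
  weight α = 5; predictions are clamped to [1e−7, 1−1e−7] before the logs,
  and the analytic gradient is zeroed where the clamp is active.

## Patch sampling and augmentation

Training draws 96³ patches (48³ in the scaled-down suite) with an expected
60 % positive share: each draw is an independent Bernoulli(0.6) event, so
the share holds in expectation rather than per batch. A positive patch
centres on a uniformly chosen voxel of a uniformly chosen ground-truth
component, jittered ±(patch/4) per axis and clipped to bounds (the jitter
keeps the lesion inside the patch); a negative patch is uniform over
origins whose window contains tissue and zero fracture voxels. Scans
without fractures warn and emit negatives only. Augmentation applies, from
one random state per sample, axis flips (p = 1/2 each), rotation up to ±15°
about one random axis, and isotropic scaling in [0.9, 1.1]; image and label
share the identical transform, the label is interpolated nearest-neighbour
and re-binarized. The rotation/scale magnitudes are unpublished details and
config-exposed.

Scans are split 7:1:2 (train/validation/test) by scan id. The checkpoint
kept is the one with the lowest validation total loss, evaluated on a
fixed seeded set of validation patches each epoch ("best" is otherwise
unspecified upstream; lowest validation loss is the package's choice). An
"epoch" is a fixed number of sampled-batch steps, not a sweep of a finite
patch list, since patches are drawn on the fly.

## Inference

Whole scans are covered by a 96³ sliding window with step 48; per axis the
final origin is end-aligned at (dim − 96) so no voxel is missed, and scans
smaller than the window are zero-padded then cropped back. Windows whose
normalized intensities are all ≤ 1e−6 contain no tissue (the −300 HU fill
maps to exactly 0) and are skipped. Overlapping predictions are fused by
voxelwise averaging over covering windows (max-fusion behind a flag; the
combination rule for overlaps is the package's choice). The fused map is
binarized at ≥ 0.4 (inclusive — the comparison direction is unspecified
upstream), 26-connected components below 300 voxels are removed (strict),
and each surviving component becomes a proposal whose confidence is the
mean *fused* probability over its voxels (post-fusion averaging is the
package's choice). Proposals sort by descending confidence, ties broken by
larger volume then lower component id.

## FROC evaluation

Ground-truth lesions are the 26-connected components of the annotation
mask. Matching is greedy in descending confidence: a proposal is a true
positive if its voxel IoU with some still-unmatched lesion strictly
exceeds 0.2 (IoU exactly 0.2 is a false positive), consuming the
highest-IoU candidate; matching is one-to-one, the standard FROC
convention, so one detection can never validate two lesions. The curve
sweeps every proposal confidence as a threshold; FPs/scan at a threshold is
total false positives divided by the number of scans (scans with zero
ground truth included). Sensitivity at rate r is the maximum sensitivity
over thresholds with FPs/scan ≤ r, zero (not interpolated) if no threshold
qualifies; it is therefore non-decreasing in r. The summary statistic is
the arithmetic mean of the sensitivities at 1/2, 1, 2, 4 and 8 FPs/scan,
reported to two decimals.

## Synthetic phantom

The phantom reproduces the structure the pipeline relies on, in simplified
geometry on a (default) 160³ grid at 1 mm isotropic spacing: an elliptical
soft-tissue thorax (40 HU) in air (−1000 HU); a posterior spine column
(600 HU, radius 6); six rib pairs as elliptical-arc tubes (radius 5) with a
~700 HU cortical shell and ~250 HU marrow core, each joined to the spine by
a straight connector so largest-component extraction keeps the whole cage;
3–5 bright debris blobs (500 HU, radius 2–4, each well below 4000 mm³ and
kept ≥ 2 voxels clear of the cage); and Gaussian noise (sd 15 HU).

Fractures are transverse bands on randomly chosen distinct ribs where the
bone intensity drops to 200 HU over an extent of 4–6 voxels, recorded
voxel-exactly in the ground-truth mask. Two deliberate choices:

* The dip value sits *above* the 180 HU extraction threshold, so a lesion
  is part of the binarized cage and can never fall out of the bone mask —
  while remaining a clear intensity disruption against the ~700 HU cortex.
  A dip below the threshold would instead rely on dilation to keep the gap
  voxels inside the mask, which bounds the representable gap width by the
  dilation reach (3 voxels from each stump under the default element);
  that is also why the default extent range stops at 6 voxels rather than
  extending to the widest clinically plausible gaps. Wider extents are
  accepted in the config for users who also widen the dilation.
* The rib radius (5 voxels ≈ realistic at 1 mm spacing) makes a
  full-cross-section band of extent 4–6 occupy ~310–470 voxels, above the
  300-voxel proposal filter, so ground-truth lesions are representable as
  detections at all.

`PhantomConfig.easy()` is the setting used by the scaled-down end-to-end
exercises: 96³ volumes, four rib pairs, 2–3 fractures of extent 5–6, noise
sd 10 HU.

What the phantom does **not** model: lungs, heart, vessels, partial-volume
blur at tissue interfaces, reconstruction-kernel texture, anatomical rib
counts and cross-section variation, displaced or comminuted fracture
morphology, or annotation noise. Consequently, passing the phantom
end-to-end test shows that the pipeline's stages compose correctly and
that the network can learn and localise a low-intensity disruption on a
curved bone — it says nothing about sensitivity on clinical CT, where
lesions are subtler and confounders are abundant.

## Scaled-down end-to-end run

The full training recipe (96³ patches, batch 16, 100 epochs, multi-GPU) is
far beyond a single-CPU exercise, so the end-to-end check trains a
base-channels-4 model on 48³ patches over 10 easy-setting phantoms
(7 train / 1 validation / 2 held-out test) for 5 epochs of 40 batch-4
steps, then evaluates FROC on the held-out pair. Augmentation is disabled
at this scale: with only 200 optimisation steps on the easy phantom its
regularisation merely delays the fit, and the smoke run is meant to check
that the stages compose and that the lesion is learnable, not that the
model generalises. These problem sizes are the package's chosen smoke
scale; the assertion thresholds (loss decreases; sensitivity at 8 FPs/scan
above 0.5) are deliberately loose because a few hundred steps only begin
to separate lesion from marrow intensity — detection typically emerges
around step 120–150 of the 200.

## Numerical and degenerate-input conventions

* All randomness flows from explicit seeds through `numpy.random.Generator`;
  per-scan phantom seeds are `seed + 1000·i`.
* Empty mask into `largest_component` → empty mask plus a warning; all-air
  scan → empty bone mask and an all-zero normalized volume.
* IoU of two empty voxel sets is undefined and rejected.
* FROC with zero ground truth over all scans is an error, not a zero.
* Checkpoints embed the full `ModelConfig`, so a saved model is
  self-describing.
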