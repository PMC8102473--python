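# Methods

## Problem and pipeline

High-resolution peripheral quantitative CT (HR-pQCT) quantifies volumetric
bone mineral density (vBMD) of hand bones at 82 µm isotropic resolution.
The clinical bottleneck is segmentation of the second metacarpal (MC):
semi-automatic expert contouring of 200–320 slices per scan takes tens of
minutes. This package implements the fully automatic alternative as a
three-stage pipeline — acquisition, segmentation, vBMD measurement — in
which a convolutional network replaces the expert contour, and validates
every stage end-to-end on synthetic calibrated phantoms.

Stages, in order:

1. **simulate** (`mcvbmd.phantom`) — generate calibrated phantom volumes
   with ground-truth masks and expert-style contour annotations.
2. **preprocess** (`mcvbmd.preprocess`) — drop slices outside the annotated
   volume of interest (VOI), resample to the network grid (512×512×80 at
   full scale), mirror left hands to a canonical right-hand orientation,
   and standardise intensities with the training split's global mean and
   variance.
3. **segment** (`mcvbmd.models`, `mcvbmd.train`) — a 2-D U-Net with a
   ResNet34-style encoder applied slice by slice, or a 3-D U-Net applied
   in one forward pass; both trained with the soft Dice loss and Adam.
4. **postprocess** (`mcvbmd.postprocess`) — mirror left-hand predictions
   back, solidify the mask, upsample to the original in-plane grid and
   re-insert the dropped slices.
5. **quantify** (`mcvbmd.quantify`) — D100: the mean calibrated density
   over all mask voxels, in mg HA/cm³, plus per-slice cross-sectional
   areas and bone volume.
6. **evaluate** (`mcvbmd.evaluate`) — overlap metrics (Dice, Jaccard,
   pixel accuracy, AUROC) and manual-vs-automatic agreement statistics
   (Pearson, Spearman, ICC, Bland–Altman).

## Phantom model

The phantom is the package's stand-in for patient scans, which cannot be
redistributed. A bone is a disk swept along a gently bowed axis: a
high-density cortical shell (default 900 mg HA/cm³) around a lower-density
trabecular interior (default 250 mg HA/cm³) in soft tissue (default
30 mg HA/cm³). The radius profile tapers linearly from proximal to distal
and narrows smoothly over the distal end, emulating the epiphyseal "delta"
region where the expert annotator stops; the stopping rule itself is
modelled as the `annotated_range` cutoff, not as true epiphyseal geometry.
Optional features: cortical erosions (spherical notches centred on the
shell surface that replace bone by background density and breach the shell,
as in arthritic bone), straight distractor bones beside the target
(imaged, never part of the mask), left/right laterality (a left phantom is
the exact column-axis mirror of its right twin, by construction), additive
Gaussian density noise (default SD 25 mg HA/cm³), and per-case slice
counts. Intensities are linked to density by an invertible linear
calibration stored with each volume; the scanner's native intensity units
are not public, so slope and intercept are synthetic but explicit.

Rasterization rule, fixed repo-wide: a voxel belongs to a region iff its
center lies inside the continuous region (closed disks; strict interior
for polygons). This makes every mask checkable against a brute-force
point-in-region count, which the tests do.

Cohort sampling draws spec fields uniformly from configurable ranges;
laterality is sampled with the clinical left-hand fraction 130/541 by
default. All sampling is reproducible from one seed.

What the phantom does *not* model: trabecular microstructure, scanner
noise spectra, beam hardening, motion artifacts, neighbouring soft-tissue
structures with bone-like density. Passing tests therefore demonstrate
that the pipeline machinery is correct and that the networks can learn
this family of shapes; they do not certify clinical performance on
patient data.

## Networks

**2-D U-Net.** Encoder: ResNet34-style residual encoder of depth 5 with
stage channels (3, 64, 64, 128, 256, 512) — a 7×7/stride-2 stem, max-pool,
then four basic-block stages with (3, 4, 6, 3) blocks. Decoder: standard
U-Net decoder with (256, 128, 64, 32, 16) channels, nearest-neighbour
upsampling, skip concatenation and two 3×3 conv-BN-ReLU layers per stage;
a 1×1 head with sigmoid produces per-pixel probabilities. Grayscale
slices are replicated to three input channels to match the encoder's
3-channel input width. The deepest feature sits at stride 32, so spatial
dims must be divisible by 2⁵ (the 512×512 and 64×64 grids both are).
ImageNet-pretrained weights are not redistributable in this build;
`pretrained=True` falls back to random (He) initialization with a warning.

**3-D U-Net.** Depth 5, channels starting at 2 and doubling per stage
(2, 4, 8, 16, 32), LeakyReLU (negative slope 0.01, configurable), dropout
with p = 0.6 in the first stage only, four 2× pools (dims divisible by
2⁴). The decoder mirrors the encoder channel sequence — the original
description specifies the encoder only, so the mirrored decoder is a
documented choice, as is batch normalisation in both networks.

**Loss.** Soft Dice, `1 − (2Σpt + ε)/(Σp + Σt + ε)` with ε = 1.0 on the
sums (standard smoothing; with ε = 0 and binary inputs it is exactly
1 − DSC, which the tests assert against the metrics module).

**Numerical substrate.** Both networks run on `mcvbmd.nn`, a small
reverse-mode autodiff engine over numpy arrays written for this package:
strided N-d convolution via im2col, 2× max pooling, 2× nearest upsampling,
batch norm composed from primitive ops, dropout, Adam. Every op is
verified against finite differences in the test suite. Training is
single-threaded-deterministic: identical seeds give bit-identical
parameter trajectories.

**Scaled-down configurations.** Full-scale training (541 cases at
512×512×80) is a GPU-scale exercise; the tested surface is the scaled
family: `width_multiplier` shrinks all channel counts (floor 2) and
`encoder_blocks=(1,1,1,1)` reduces the residual stages to one block each.
The standard desk-scale experiment trains a width-0.125 2-D U-Net on 24
noise-free 64×64×16 phantom cases (70/20/10 split, Adam, lr 1e-3, batch 4,
12 epochs) and evaluates held-out Dice; it reaches ≥ 0.95 in a few minutes
on one CPU. A single-case overfit sanity check (ordered slice cycling,
lr 3e-2, 200 steps) drives the training Dice loss below 0.05. The demo
pipeline (`mcvbmd.pipeline.demo_config`) uses 12 noisy 64×64×32 cases with
varying densities and erosions (ranges chosen so the cohort's D100 spread
matches the clinical standard deviation of about 43 mg HA/cm³), 12 epochs,
and — as in the clinical protocol for non-pretrained networks — repeats
the training three times with perturbed seeds, keeping the best run by
validation Dice.

## Training protocol

Splits are drawn by seeded shuffling with per-split counts
`floor(fraction·N)`; with 541 cases and fractions 0.70/0.20/0.10 this
gives 378/108/54 with one case left unassigned — the default remainder
policy, chosen to reproduce those counts exactly (`to_train` is the
alternative). Full-scale defaults follow the clinical protocol: Adam with
default hyperparameters, lr 1e-5/batch 4 for 2-D, lr 1e-4/batch 1 for
3-D; non-pretrained runs can be repeated (`n_repeats`) with the seed
perturbed per repeat, keeping the best run by validation Dice. Epoch
budget and early stopping (patience on validation Dice) are not specified
clinically and default to 100/15. Normalization statistics are computed
from training-split voxels only; `NormalizationStats` records the
contributing case ids and `train_model` refuses stats that contain any
validation or test case (leakage guard).

## Post-processing choices

Hole topology is judged per slice in 2-D, matching the slice-wise
annotation workflow. `fill_holes` defaults to a slice-wise
border-connected flood fill: interior cavities become foreground,
notches reaching the slice border (erosions) stay open, the outer
boundary never moves, and the operation is idempotent and monotone. A
morphological active-contour (Chan–Vese without edges) refinement pass is
available (`macwe_iters > 0`) for smoothing ragged prediction boundaries;
its output is clipped to a `tol`-voxel band (default 1) around the filled
input and unioned with it, so solidity and the boundary tolerance still
hold. It is off by default because repeated application can legitimately
add boundary voxels inside the band, i.e. it is not idempotent.

Mask resampling anywhere in the pipeline is trilinear followed by
thresholding at 0.5 (smoother boundaries than nearest-neighbour at the
3× in-plane downscale; thresholding restores binarity). Binarization of
probabilities uses a strict `> 0.5` rule; exact ties go to background.

## Quantification and agreement conventions

* D100 is the plain mean density over mask voxels. The scanner's exact
  definition (e.g. boundary peeling) is not public; the mask mean is the
  only unit-consistent reading of a density reported in mg HA/cm³.
* Slices with zero mask voxels are excluded from the mean slice area.
* An empty segmentation raises an explicit error rather than yielding NaN.
* IOU is the standard Jaccard index |X∩Y|/|X∪Y|. A printed variant of the
  formula omitting the union correction (equal to DSC/2) is inconsistent
  with the relationship between reported Dice and IOU values and is treated
  as a typo; the identity IOU = DSC/(2−DSC) is property-tested.
* Empty-vs-empty overlap is defined as 1.0; empty-vs-nonempty as 0.0.
* Bland–Altman differences are `automatic − manual` (a network that
  underestimates density shows a negative bias), with limits of agreement
  mean ± 1.96·SD.
* ICC defaults to the two-way random-effects, absolute-agreement,
  single-measurement form (ICC(2,1), pingouin's ICC(A,1)); the variant is
  config-exposed.

## Known limitations

* No GPU path: full-scale (512×512×80, ResNet34) training is out of reach
  of the numpy engine; inference at that scale works but is slow.
* The phantom's simple geometry means segmentation Dice values near 1.0
  are expected and say nothing about performance on arthritic anatomy.
* Timing comparisons with the manual workflow are hardware-bound and are
  logged for information only, never asserted.
* Proprietary scanner formats (AIM/ISQ/GOBJ) and DICOM are out of scope;
  volumes travel as NIfTI/MetaImage with JSON sidecars, contours as a
  documented JSON format.
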