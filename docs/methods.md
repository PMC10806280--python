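# Methods

This note records the models and procedures `marrowseg` implements, the
conventions and defaults it fixes where a design choice was genuinely open,
and what its phantom-based validation does and does not demonstrate.

## Data model and conventions

All volumes are 3-D scalar grids indexed `(z, y, x)` with `z` the axial
slice index; voxel spacing is carried as `(dx, dy, dz)` in mm.  NIfTI is
the interchange format (one file per channel; masks as unsigned 8-bit),
with spacing taken from the header.  The full-scale geometry the package
targets is an abdominal slab of 44 axial slices at 4.5 mm thickness and
2.2 mm in-plane resolution; desk-scale work uses `(24, 48, 48)` or
`(24, 24, 24)` grids with the same spacing metadata.

Normalized coordinates map the centre of the first voxel of an axis to −1
and the centre of the last to +1, linearly in between.  This single
convention is shared by the phantom ground truth, the coordinate grid under
the probability map, the ROI-centre regression and the crop placement, and
is what makes the centre errors of different volumes comparable.

The Dice coefficient is `2|A∩B|/(|A|+|B|)`.  Two empty masks score 1.0
(identical sets) and one empty mask against a non-empty one scores 0.0,
which makes the metric total; evaluation never rewards an empty prediction
against a non-empty truth.

## The ROI-attention segmentation network

**Encoder.**  Four resolution levels.  Levels 1–3 apply a convolutional
block (3-D conv + instance norm + ReLU), then a CBAM convolutional layer,
then a stride-2 3×3×3 convolution for downsampling.  The deepest block has
two CBAM layers with an embedded-Gaussian non-local layer between them
(embedding width half the channel count; its output projection is
initialized to zero so the block starts as the identity).  The CBAM layer
keeps the standard channel-attention branch (shared two-layer MLP over
global average- and max-pooled channel vectors, sigmoid gate) but replaces
the pooled two-map spatial branch with a single-channel map from a 1×1×1
convolution; the raw (pre-sigmoid) map is exported for fusion, and its
sigmoid gates the features.

**Detection.**  The five raw attention maps (one per CBAM layer in levels
1–3, two from the deepest block) are trilinearly resized to a fixed cube
(96³ at full scale, 24³ at test scale) and fused by a two-layer 1×1×1 CNN
(hidden width 8, ReLU) into a single logit map, followed by a softmax over
*all* voxels.  The ROI centre is the expectation of the normalized
coordinate grid under this probability map — a soft-argmax, differentiable
in the map.

**Crop and decode.**  The centre is mapped to each level's fractional
voxel position; a cube of the level's ROI size (halving with depth:
32/16/8/4 full scale, 16/8/4/2 test scale) is placed centred there, the
corner rounded with ties toward the lower index, and shifted to lie fully
inside the grid rather than zero-padded — clamping keeps crops filled with
valid feature content.  The decoder upsamples from the deepest crop with
one conv block per level (skip connections from the crops) and a 1×1×1
two-class head.  The ROI segmentation is implanted back into the full
volume; everything outside the ROI is background.

**Input normalization.**  Volumes are z-scored per volume before encoding.
Shapes not divisible by `2^(levels−1)` are symmetrically zero-padded and
the output un-padded (44 slices → 48), transparently in `predict`.

**Lightweight claim.**  Because the decoder processes only ROI crops it can
be shallow (one conv block per level); the package asserts at test time
that the whole ROI-attention network, including its attention machinery,
has strictly fewer parameters than the size-matched conventional U-Net
comparator with its standard two-conv decoder blocks.

## The comparator

The conventional 3-D U-Net uses the identical conv blocks (conv + instance
norm + ReLU, stride-2 conv downsampling) with two convolutions per encoder
and decoder stage and no CBAM/non-local/ROI machinery, and decodes the full
volume.  The comparison between the two therefore isolates the
ROI-attention mechanism rather than block engineering.

## Losses

`L = Lseg + λ1·LROI + λ2·Lloc`, defaults λ1 = λ2 = 1.

* `Lseg`: multi-class soft Dice over the full volume with class weights
  proportional to the reciprocal of the target voxel count.  Counts are
  inflated by one voxel before the reciprocal so an absent class keeps a
  finite weight, and weights are normalized to sum to one (normalization
  changes the magnitude, not the minimizer, and makes the loss comparable
  across grids).
* `LROI`: plain soft Dice over the ROI.  The target is the ground-truth
  mask cropped at the *predicted* centre with the crop index detached, so
  prediction and target stay spatially aligned and centre gradients flow
  only through `Lloc`.  Placing the training ROI at the true centre instead
  was the open alternative; the predicted-centre choice matches what
  inference does.
* `Lloc`: squared Euclidean distance between predicted and true centres in
  normalized coordinates — the simplest smooth form, bounded on `[-1,1]³`.
* Dice smoothing `ε = 1e-6` in numerator and denominator, stated so
  independent oracles can reproduce values exactly.

## Training

Adam (β₁ = 0.9, β₂ = 0.999), learning rate 1e-3, batch size 2, whole
volumes per step, no augmentation (targets are localized by the detection
branch, so random cropping is unnecessary).  A single integer seed drives
weight initialization, data order and phantom noise; all operations are
deterministic, so runs are exactly reproducible.  Training aborts with a
diagnostic if the loss becomes non-finite.  Loss curves are noisy per step;
the monotonicity contract asserted is median-of-last-10 < median-of-first-10.

The implementation is functional numpy differentiated with `autograd`.
The 3-D convolution is a custom primitive using a shift-and-add forward
(k³ channel-mixing matmuls over shifted views) with hand-coded reverse
passes — a transposed convolution for the input gradient and a correlation
for the weight gradient — which keeps CPU training of the desk-scale
configuration at a few minutes per experiment.

## Phantoms

A phantom is one synthetic two-point Dixon slab: a water-dominant noisy
background (background fat fraction 20%) containing one bright-fat target —
segmentation operates on the fat channel, so targets must be fat-bright.
Region geometries: a stack of separated blocks (spine), a sphere (femoral
head), a sphere with a neck cylinder (total hip), and a thin axial tube of
9 voxels per slice (diaphysis), whose default size of 100 voxels matches
the cohort-mean diaphysis segmentation volume; full-scale defaults for the
other regions likewise use the cohort-mean volumes (spine 2244, total hip
1248, femoral head 810 voxels).

Channel intensities are built so that `100·fat/(fat+water)` inside the
target equals the configured fat fraction exactly in the noiseless case
(the interior total intensity is a power of two, so the ratio involves no
rounding); additive Gaussian noise (default SD 5 against interior signal
512 and background 128) is applied per channel and clipped at zero.
Datasets jitter target positions uniformly over the largest box that keeps
the target inside the volume and sizes by ±20%, with per-sample seeds
derived from one master seed.

What the phantoms do *not* emulate: anatomical bone shape, intensity
inhomogeneity, partial-volume boundaries, fat–water swaps (beyond an
optional channel-swap flag) and protocol/data-structure faults.  Passing
phantom tests therefore demonstrates that the architecture, losses, QC
rules and FF arithmetic behave as specified and that the detect-crop-decode
mechanism trains end to end — not that any particular Dice level transfers
to clinical cohorts.

## Segmentation QC

Cleanup first: 26-connected components of exactly one voxel are removed;
internal cavities are filled with 6-connected hole filling.  "Joining"
discontinuous output is interpreted as union-into-one-VOI plus cavity
filling — morphological bridging of separated components would fabricate
voxels and is deliberately not done.  Classification uses voxel counts:
`Empty` for zero voxels, `Small` when volume is strictly below
mean − 2.5·SD of a reference set, otherwise `OK`; the centre-of-mass rule
flags a mask whose COM is strictly more than 3 SD from the reference mean
on *any* axis (per-axis rather than Euclidean — stricter and simpler to
state).  Reference statistics use sample SD (ddof = 1) from at least two
non-empty masks.  Voxel counts, not mm³, are the thresholded quantity;
mm³ is derivable through the spacing.

## Fat-fraction mapping and BMFF

"Nearest-neighbour smoothing" is implemented as a 3×3 in-plane mean filter
(including the centre voxel; edge voxels average their available
neighbours).  In-plane was chosen because slices are thick (4.5 mm)
relative to the in-plane spacing (2.2 mm), so a 3-D kernel would mix
anatomically distant tissue.  Smoothing applies to the fat and water
channels before mapping, never to masks.

`FF = 100·fat/(fat+water)` per voxel; `fat + water = 0` yields a missing
value excluded from means (reporting 0 would bias BMFF downward).  Before
averaging, masks are eroded by one voxel in plane with the 4-connected
cross — the minimal single-boundary-voxel erosion — except the diaphysis,
whose few-voxel cross-section would be eliminated.  If erosion leaves no
usable voxel the extraction raises an explicit error advising a fall back
to the un-eroded mask rather than silently switching.

Two-point data does not support T2*-corrected PDFF; the package computes
the dual-echo BMFF only.

## Validation problem sizes

The bundled experiments run on `24³` phantoms with the test-scale network
(channels 8/16/32/64, attention cube 24³, ROI sizes 16/8/4/2): 40 training
and 8 held-out diaphysis phantoms, 12 epochs for each architecture; the
end-to-end demo uses 10–12 training phantoms and 6–8 epochs.  These sizes
were chosen so a full experiment, including the comparator, completes in a
few minutes on one CPU while still exercising every architectural path at
realistic class imbalance (≈100 foreground voxels in 13 824).

## Known limitations

* Binary segmentation only; one structure per volume (the detection step
  regresses a single centre).
* The phantom background is spatially homogeneous; the attention fusion
  has an easier detection task than on clinical data.
* The non-local layer runs on the coarsest grid only, as memory for an
  N²-attention over finer grids would be prohibitive.
* No learning-rate schedules, early stopping, augmentation or mixed
  precision; training is deliberately small and deterministic.
* For structures only a few voxels across, the pre-mapping in-plane
  smoothing mixes background signal into boundary voxels, and the
  diaphysis mask is deliberately not eroded — so diaphyseal BMFF carries a
  partial-volume bias even under a perfect segmentation.  The phantoms'
  sharp boundaries make this visible directly (the acceptance run reports
  it as the BMFF error through trained segmentations); in vivo the same
  mechanism is a known caveat of thin-structure fat fractions.
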