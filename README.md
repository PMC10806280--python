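# marrowseg

Automated bone-marrow segmentation and fat-fraction quantification from
two-point Dixon MRI, built around a lightweight attention-gated ROI 3-D
U-Net for detecting and segmenting *small* structures inside *large*
volumetric images.

## The problem

Bone marrow adipose tissue is quantified in vivo as the bone marrow fat
fraction (BMFF) from chemical-shift (Dixon) MRI, at skeletal sites such as
the vertebral column, femoral head, total hip and femoral diaphysis.  At
cohort scale the bottleneck is segmentation: the diaphyseal marrow cavity
occupies only a few voxels per axial slice of a whole-abdomen acquisition,
and a conventional 3-D U-Net decoding the full volume tends to collapse to
all-background under that class imbalance.

`marrowseg` addresses this with a detect-then-segment network:

1. An encoder with four resolution levels whose blocks carry a modified
   convolutional block attention module (CBAM): channel attention as usual,
   but the spatial branch reduced to a single-channel map from a 1×1×1
   convolution.  The deepest block holds an embedded-Gaussian non-local
   layer between two CBAM layers.
2. The five raw spatial-attention maps are resized to a common cube and
   fused by a small 1×1×1 CNN with a softmax over **all** voxels, giving a
   spatial probability map `P`.
3. The ROI centre is the soft-argmax
   `(x, y, z)_ROI = Σ P ⊙ (u, v, w)` over a coordinate grid normalized to
   `[-1, 1]` — a differentiable detection step.
4. Cubes (sizes halving with depth, e.g. 32/16/8/4) are cropped from every
   encoder level around that centre; only these crops are decoded, and the
   ROI segmentation is implanted back into the full volume.

Training minimizes `L = Lseg + λ1·LROI + λ2·Lloc` (defaults λ1 = λ2 = 1):
a reciprocal-voxel-count weighted Dice loss over the full volume, a plain
Dice loss over the ROI, and the squared normalized distance between the
predicted and true centres.

Around the network sit the steps that turn a segmentation into a biomarker:
segmentation QC (single-voxel removal, cavity filling, 3-SD centre-of-mass
outlier flagging, strict 2.5-SD "Small"/"Empty" classification), two-point
Dixon fat-fraction mapping `FF = 100·fat/(fat+water)` with in-plane
smoothing, and per-VOI BMFF extraction with a one-voxel in-plane erosion
that is skipped for the thin diaphysis.

No patient data ships with the package: a seeded phantom generator emulates
the slab geometry (44 axial slices at 4.5 mm, 2.2 mm in-plane at full
scale) with known masks, centres and true fat fractions, so the entire
pipeline is trainable and testable on a desktop CPU.  The networks are
implemented as pure numpy functions differentiated with `autograd`, with a
hand-coded shift-and-add 3-D convolution primitive.

## Worked example

Train the ROI-attention network on 20 thin-tube phantoms and evaluate it
on 4 held-out ones (about two minutes on one CPU):

```bash
marrowseg train --model roi_attention --region diaphysis \
    --n-train 20 --epochs 12 --seed 0 --checkpoint ckpt.npz
marrowseg evaluate --checkpoint ckpt.npz --region diaphysis --n-val 4 --seed 10000
```

which prints, for that seed:

```json
{
  "region": "diaphysis",
  "per_sample_dice": [1.0, 1.0, 1.0, 1.0],
  "mean_dice": 1.0,
  "mean_centre_error": 0.024842259568141588
}
```

`mean_dice` is the overlap `2|A∩B|/(|A|+|B|)` between predicted and true
masks on held-out phantoms; `mean_centre_error` is the Euclidean distance
between predicted and true ROI centres in `[-1, 1]` normalized units.

The full pipeline — phantoms → training → segmentation → QC → FF mapping →
BMFF extraction, with provenance sidecars — runs as:

```bash
marrowseg demo --outdir runs/demo --seed 0
```

and ends with a `summary.json` reporting held-out Dice, QC status counts
and the recovered BMFF against the configured ground truth.

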