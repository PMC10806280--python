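"""Attention-gated ROI 3-D U-Net for small-structure segmentation.

The model addresses a specific failure mode of conventional 3-D U-Nets: when
the foreground occupies a tiny fraction of a large volume (a thin femoral
shaft is only a few voxels per axial slice), a full-volume decoder tends to
collapse to all-background.  Instead of decoding the whole volume, this
network

1. encodes the volume through four resolution levels whose convolutional
   blocks carry a modified CBAM attention layer (channel attention as in
   CBAM; spatial attention reduced to a single-channel map produced by a
   1x1x1 convolution), with an embedded-Gaussian non-local block in the
   deepest level;
2. resizes the five raw spatial-attention maps (one per CBAM layer in
   levels 1-3, two in the deepest block) to a fixed cube and fuses them
   through a small 1x1x1 CNN followed by a softmax over *all* voxels,
   yielding a spatial probability map ``P``;
3. takes the expected value of a [-1, 1]-normalized coordinate grid under
   ``P`` (a soft-argmax) as the ROI centre;
4. crops a cube from every encoder level around that centre (sizes halving
   with depth), decodes only the cropped features, and implants the ROI
   segmentation back into the full volume.

The decoder therefore only ever sees the ROI, which is what makes the model
light-weight relative to a size-matched conventional U-Net.

All computations are pure functions of a parameter dict so the whole forward
pass can be differentiated with ``autograd``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import autograd.numpy as np
import numpy as onp

from ..volumes import LabelMask, Volume3D
from . import ops
from .ops import (
    conv3d,
    detach,
    instance_norm,
    pad_to,
    relu,
    sigmoid,
    softmax_all,
    softmax_channels,
    trilinear_resize,
    upsample2,
)

__all__ = [
    "NetworkConfig",
    "CoordinateGrid",
    "RoiCentre",
    "EncoderState",
    "RoiCrops",
    "RoiAttentionUNet",
    "locate_roi",
    "roi_corner",
    "implant_roi",
    "pad_to_divisible",
]


@dataclass(frozen=True)
class NetworkConfig:
    """Architecture hyper-parameters.

    ``roi_sizes`` must halve with depth and the attention cube must be at
    least as large as the top-level ROI.
    """

    levels: int = 4
    channels: tuple[int, ...] = (32, 64, 128, 256)
    attention_map_size: int = 96
    roi_sizes: tuple[int, ...] = (32, 16, 8, 4)
    num_classes: int = 2
    cbam_reduction: int = 4
    fusion_hidden: int = 8

    def __post_init__(self) -> None:
        if len(self.channels) != self.levels:
            raise ValueError("channels must list one width per level")
        if len(self.roi_sizes) != self.levels:
            raise ValueError("roi_sizes must list one size per level")
        for k in range(self.levels - 1):
            if self.roi_sizes[k + 1] * 2 != self.roi_sizes[k]:
                raise ValueError(f"roi_sizes must halve per level, got {self.roi_sizes}")
        if self.attention_map_size < self.roi_sizes[0]:
            raise ValueError("attention_map_size must be >= roi_sizes[0]")
        if self.num_classes != 2:
            raise ValueError("only binary (background/foreground) segmentation is supported")

    @classmethod
    def test_scale(cls) -> "NetworkConfig":
        """Desk-scale configuration for CPU training on small phantoms."""
        return cls(
            levels=4,
            channels=(8, 16, 32, 64),
            attention_map_size=24,
            roi_sizes=(16, 8, 4, 2),
            cbam_reduction=2,
        )


@dataclass
class CoordinateGrid:
    """Per-voxel normalized coordinates over a 3-D grid.

    ``u`` varies along the x (last) axis, ``v`` along y, ``w`` along z; each
    runs linearly from -1 at the centre of the first voxel to +1 at the
    centre of the last.
    """

    u: onp.ndarray
    v: onp.ndarray
    w: onp.ndarray

    @classmethod
    def for_shape(cls, shape) -> "CoordinateGrid":
        nz, ny, nx = shape
        az = onp.linspace(-1.0, 1.0, nz) if nz > 1 else onp.zeros(1)
        ay = onp.linspace(-1.0, 1.0, ny) if ny > 1 else onp.zeros(1)
        ax = onp.linspace(-1.0, 1.0, nx) if nx > 1 else onp.zeros(1)
        w, v, u = onp.meshgrid(az, ay, ax, indexing="ij")
        return cls(u=u, v=v, w=w)


@dataclass
class RoiCentre:
    """Predicted ROI centre in normalized [-1, 1] coordinates."""

    x: float
    y: float
    z: float

    def as_xyz(self):
        return (self.x, self.y, self.z)

    def as_zyx(self):
        return (self.z, self.y, self.x)


@dataclass
class EncoderState:
    """Per-level feature grids plus the five resized raw attention maps."""

    features: list
    attention_maps: list
    input_shape: tuple[int, int, int]


@dataclass
class RoiCrops:
    """Cropped per-level features and the integer corner of each crop."""

    features: list
    corners: list  # (z, y, x) integer corner per level


def normalized_to_voxel(c: float, size: int) -> float:
    """Map a normalized coordinate to a (fractional) voxel index."""
    if size == 1:
        return 0.0
    return (c + 1.0) / 2.0 * (size - 1)


def voxel_to_normalized(v: float, size: int) -> float:
    if size == 1:
        return 0.0
    return 2.0 * v / (size - 1) - 1.0


def roi_corner(centre_zyx, grid_shape, size: int) -> tuple[int, int, int]:
    """Lowest-index corner of a ``size``-cube centred at a normalized centre.

    The cube is centred at the fractional voxel position of the centre,
    rounded with ties toward the lower index, then shifted (clamped) to lie
    fully inside the grid.
    """
    corner = []
    for ax in range(3):
        s = int(grid_shape[ax])
        if size > s:
            raise ValueError(f"ROI size {size} exceeds grid extent {s} on axis {ax}")
        v = normalized_to_voxel(float(centre_zyx[ax]), s)
        lo = math.ceil(v - (size - 1) / 2.0 - 0.5)  # round half toward lower index
        lo = min(max(lo, 0), s - size)
        corner.append(int(lo))
    return tuple(corner)


def locate_roi(P, grid: CoordinateGrid) -> RoiCentre:
    """Soft-argmax: the expected coordinate of the grid under ``P``.

    ``P`` must be normalized (sum 1 within 1e-3); the result is
    differentiable with respect to ``P``.
    """
    p_val = detach(P)
    if p_val.shape != grid.u.shape:
        raise ValueError(f"P shape {p_val.shape} does not match grid {grid.u.shape}")
    if abs(float(onp.sum(p_val)) - 1.0) > 1e-3:
        raise ValueError("probability map is not normalized (|sum - 1| > 1e-3)")
    cx = np.sum(P * grid.u)
    cy = np.sum(P * grid.v)
    cz = np.sum(P * grid.w)
    return RoiCentre(x=cx, y=cy, z=cz)


def implant_roi(roi_seg, corner, full_shape, spacing=(2.2, 2.2, 4.5)) -> LabelMask:
    """Place an ROI segmentation back into the full volume.

    ``roi_seg`` is either per-class scores ``(num_classes, r, r, r)`` (argmax
    is taken over classes) or an already-binary ``(r, r, r)`` block.  Voxels
    outside the ROI are background.
    """
    roi_seg = onp.asarray(detach(roi_seg))
    if roi_seg.ndim == 4:
        block = onp.argmax(roi_seg, axis=0).astype(onp.uint8)
    elif roi_seg.ndim == 3:
        block = (roi_seg > 0).astype(onp.uint8)
    else:
        raise ValueError(f"roi_seg must be 3-D or 4-D, got ndim={roi_seg.ndim}")
    full = onp.zeros(tuple(full_shape), dtype=onp.uint8)
    z, y, x = (int(c) for c in corner)
    dz, dy, dx = block.shape
    if z + dz > full_shape[0] or y + dy > full_shape[1] or x + dx > full_shape[2]:
        raise ValueError("ROI does not fit inside the full volume at the given corner")
    full[z : z + dz, y : y + dy, x : x + dx] = block
    return LabelMask(full, spacing)


def pad_to_divisible(data: onp.ndarray, divisor: int):
    """Symmetrically zero-pad each axis up to a multiple of ``divisor``.

    Returns the padded array and the low-side pad widths per axis.
    """
    pads = []
    for s in data.shape:
        target = ((s + divisor - 1) // divisor) * divisor
        lo = (target - s) // 2
        pads.append((lo, target - s - lo))
    out = onp.pad(data, pads, mode="constant")
    return out, tuple(p[0] for p in pads)


@dataclass
class ForwardPass:
    """Every intermediate the composite loss needs, possibly autograd-traced."""

    prob_map: object
    centre: RoiCentre
    crops: RoiCrops
    roi_logits: object
    roi_fg_prob: object
    full_fg_prob: object
    encoder: EncoderState


@dataclass
class PredictResult:
    mask: LabelMask
    centre: RoiCentre
    prob_map: onp.ndarray
    roi_corner: tuple[int, int, int]


class RoiAttentionUNet:
    """The attention-gated ROI U-Net as a parameter dict + pure functions."""

    def __init__(self, cfg: NetworkConfig | None = None):
        self.cfg = cfg or NetworkConfig()

    # ------------------------------------------------------------------ #
    # parameters
    # ------------------------------------------------------------------ #
    def init_params(self, seed: int = 0) -> dict:
        rng = onp.random.default_rng(seed)
        cfg = self.cfg
        p: dict[str, onp.ndarray] = {}

        def conv_block(name, cin, cout, k=3):
            p[f"{name}_w"] = ops.he_init(rng, (cout, cin, k, k, k), cin * k**3)
            p[f"{name}_b"] = onp.zeros(cout)
            p[f"{name}_g"] = onp.ones(cout)
            p[f"{name}_bb"] = onp.zeros(cout)

        def cbam_layer(name, c):
            conv_block(name, c, c)
            hidden = max(1, c // cfg.cbam_reduction)
            p[f"{name}_ca1_w"] = ops.he_init(rng, (hidden, c), c)
            p[f"{name}_ca1_b"] = onp.zeros(hidden)
            p[f"{name}_ca2_w"] = ops.he_init(rng, (c, hidden), hidden)
            p[f"{name}_ca2_b"] = onp.zeros(c)
            p[f"{name}_sa_w"] = ops.he_init(rng, (1, c, 1, 1, 1), c)
            p[f"{name}_sa_b"] = onp.zeros(1)

        chans = cfg.channels
        conv_block("enc0_conv", 1, chans[0])
        cbam_layer("enc0_cbam", chans[0])
        for k in range(1, cfg.levels - 1):
            conv_block(f"enc{k}_conv", chans[k], chans[k])
            cbam_layer(f"enc{k}_cbam", chans[k])
        last = cfg.levels - 1
        cbam_layer(f"enc{last}_cbam_a", chans[last])
        cbam_layer(f"enc{last}_cbam_b", chans[last])
        for k in range(cfg.levels - 1):
            conv_block(f"down{k}", chans[k], chans[k + 1])

        # non-local block on the coarsest grid (embedded Gaussian)
        ce = max(1, chans[last] // 2)
        p["nl_theta_w"] = ops.he_init(rng, (ce, chans[last]), chans[last])
        p["nl_phi_w"] = ops.he_init(rng, (ce, chans[last]), chans[last])
        p["nl_g_w"] = ops.he_init(rng, (ce, chans[last]), chans[last])
        p["nl_out_w"] = onp.zeros((chans[last], ce))  # residual starts as identity
        p["nl_out_b"] = onp.zeros(chans[last])

        # mini fusion CNN: 5 maps -> hidden -> 1 logit per voxel
        p["fuse1_w"] = ops.he_init(rng, (cfg.fusion_hidden, cfg.levels + 1), cfg.levels + 1)
        p["fuse1_b"] = onp.zeros(cfg.fusion_hidden)
        p["fuse2_w"] = ops.he_init(rng, (1, cfg.fusion_hidden), cfg.fusion_hidden)
        p["fuse2_b"] = onp.zeros(1)

        # decoder: one conv block per level above the deepest, then 1x1 head
        for k in range(cfg.levels - 2, -1, -1):
            conv_block(f"dec{k}", chans[k + 1] + chans[k], chans[k])
        p["head_w"] = ops.he_init(rng, (cfg.num_classes, chans[0], 1, 1, 1), chans[0])
        p["head_b"] = onp.zeros(cfg.num_classes)
        return p

    @staticmethod
    def parameter_count(params: dict) -> int:
        return int(sum(onp.asarray(v).size for v in params.values()))

    # ------------------------------------------------------------------ #
    # building blocks
    # ------------------------------------------------------------------ #
    def _conv_block(self, p, name, x, stride=1):
        x = conv3d(x, p[f"{name}_w"], p[f"{name}_b"], stride=stride)
        x = instance_norm(x, p[f"{name}_g"], p[f"{name}_bb"])
        return relu(x)

    def _cbam(self, p, name, x):
        """CBAM conv layer: conv block, channel attention, 1x1x1 spatial map."""
        h = self._conv_block(p, name, x)
        avg = np.mean(h, axis=(1, 2, 3))
        mx = np.max(h, axis=(1, 2, 3))

        def mlp(v):
            return np.dot(p[f"{name}_ca2_w"], relu(np.dot(p[f"{name}_ca1_w"], v) + p[f"{name}_ca1_b"])) + p[f"{name}_ca2_b"]

        scale = sigmoid(mlp(avg) + mlp(mx))
        h = h * scale[:, None, None, None]
        s = conv3d(h, p[f"{name}_sa_w"], p[f"{name}_sa_b"])  # (1, D, H, W) raw logits
        h = h * sigmoid(s)
        return h, s[0]

    def _non_local(self, p, x):
        c = x.shape[0]
        n = int(onp.prod(x.shape[1:]))
        f = np.reshape(x, (c, n))
        theta = np.dot(p["nl_theta_w"], f)
        phi = np.dot(p["nl_phi_w"], f)
        g = np.dot(p["nl_g_w"], f)
        logits = np.dot(theta.T, phi) / np.sqrt(theta.shape[0])
        m = np.max(logits, axis=1, keepdims=True)
        e = np.exp(logits - m)
        att = e / np.sum(e, axis=1, keepdims=True)  # (n, n), rows sum to 1
        y = np.dot(g, att.T)
        out = f + np.dot(p["nl_out_w"], y) + p["nl_out_b"][:, None]
        return np.reshape(out, x.shape)

    # ------------------------------------------------------------------ #
    # the five spec operations
    # ------------------------------------------------------------------ #
    def encode(self, params: dict, vol) -> EncoderState:
        """Run the encoder; returns per-level features and 5 resized attention maps."""
        cfg = self.cfg
        data = vol.data if isinstance(vol, Volume3D) else vol
        shape = tuple(int(s) for s in data.shape[-3:])
        div = 2 ** (cfg.levels - 1)
        if any(s % div for s in shape):
            raise ValueError(
                f"input shape {shape} is not divisible by 2^(levels-1)={div}; "
                "pad the volume (see pad_to_divisible) before encoding"
            )
        x = np.reshape(data, (1,) + shape)
        mu = np.mean(x)
        sd = np.sqrt(np.mean((x - mu) ** 2)) + 1e-8
        x = (x - mu) / sd

        t = (cfg.attention_map_size,) * 3
        features, maps = [], []
        f, s = None, None
        for k in range(cfg.levels - 1):
            name = f"enc{k}_conv"
            x = self._conv_block(params, name, x)
            f, s = self._cbam(params, f"enc{k}_cbam", x)
            features.append(f)
            maps.append(trilinear_resize(s, t))
            x = self._conv_block(params, f"down{k}", f, stride=2)
        last = cfg.levels - 1
        f, s = self._cbam(params, f"enc{last}_cbam_a", x)
        maps.append(trilinear_resize(s, t))
        f = self._non_local(params, f)
        f, s = self._cbam(params, f"enc{last}_cbam_b", f)
        maps.append(trilinear_resize(s, t))
        features.append(f)
        return EncoderState(features=features, attention_maps=maps, input_shape=shape)

    def fuse_attention(self, params: dict, maps) -> object:
        """Fuse the 5 resized attention maps into a spatial probability map."""
        expected = self.cfg.levels + 1
        if len(maps) != expected:
            raise ValueError(f"expected {expected} attention maps, got {len(maps)}")
        stacked = np.concatenate([m[None] for m in maps], axis=0)
        nmaps = stacked.shape[0]
        flat = np.reshape(stacked, (nmaps, -1))
        h = relu(np.dot(params["fuse1_w"], flat) + params["fuse1_b"][:, None])
        logit = np.dot(params["fuse2_w"], h) + params["fuse2_b"][:, None]
        logit = np.reshape(logit, maps[0].shape)
        return softmax_all(logit)

    def crop_roi(self, state: EncoderState, centre: RoiCentre, detach_centre: bool = True) -> RoiCrops:
        """Crop a cube from every encoder level around the (detached) centre."""
        cfg = self.cfg
        czyx = [detach(c) for c in centre.as_zyx()] if detach_centre else centre.as_zyx()
        crops, corners = [], []
        for k in range(cfg.levels):
            fk = state.features[k]
            size = cfg.roi_sizes[k]
            corner = roi_corner(czyx, fk.shape[1:], size)
            z, y, x = corner
            crops.append(fk[:, z : z + size, y : y + size, x : x + size])
            corners.append(corner)
        return RoiCrops(features=crops, corners=corners)

    def decode(self, params: dict, crops: RoiCrops) -> object:
        """Decode the cropped features into per-class ROI scores."""
        cfg = self.cfg
        expect = [(cfg.channels[k], cfg.roi_sizes[k]) for k in range(cfg.levels)]
        for k, f in enumerate(crops.features):
            c, s = expect[k]
            if f.shape != (c, s, s, s):
                raise ValueError(
                    f"crop {k} has shape {f.shape}, expected {(c, s, s, s)}"
                )
        x = crops.features[-1]
        for k in range(cfg.levels - 2, -1, -1):
            x = np.concatenate([upsample2(x), crops.features[k]], axis=0)
            x = self._conv_block(params, f"dec{k}", x)
        return conv3d(x, params["head_w"], params["head_b"])

    def forward(self, params: dict, vol) -> ForwardPass:
        """Full forward pass exposing every intermediate needed by the loss."""
        state = self.encode(params, vol)
        P = self.fuse_attention(params, state.attention_maps)
        grid = CoordinateGrid.for_shape(detach(P).shape)
        centre = locate_roi(P, grid)
        crops = self.crop_roi(state, centre)
        roi_logits = self.decode(params, crops)
        probs = softmax_channels(roi_logits)
        roi_fg = probs[1]
        full_fg = pad_to(roi_fg, crops.corners[0], state.input_shape)
        return ForwardPass(
            prob_map=P,
            centre=centre,
            crops=crops,
            roi_logits=roi_logits,
            roi_fg_prob=roi_fg,
            full_fg_prob=full_fg,
            encoder=state,
        )

    # ------------------------------------------------------------------ #
    # inference
    # ------------------------------------------------------------------ #
    def predict(self, params: dict, vol: Volume3D) -> PredictResult:
        """Segment a volume, transparently padding non-divisible shapes."""
        div = 2 ** (self.cfg.levels - 1)
        data = onp.asarray(vol.data, dtype=float)
        orig_shape = data.shape
        padded, lo = pad_to_divisible(data, div)
        out = self.forward(params, padded)
        mask_padded = implant_roi(
            detach(out.roi_logits), out.crops.corners[0], padded.shape, vol.spacing
        )
        sl = tuple(slice(lo[a], lo[a] + orig_shape[a]) for a in range(3))
        mask = LabelMask(mask_padded.data[sl], vol.spacing)
        # map the centre from padded-grid to original-grid normalized coords
        czyx_p = [float(detach(c)) for c in out.centre.as_zyx()]
        czyx = []
        for ax in range(3):
            v = normalized_to_voxel(czyx_p[ax], padded.shape[ax]) - lo[ax]
            czyx.append(voxel_to_normalized(v, orig_shape[ax]))
        centre = RoiCentre(x=czyx[2], y=czyx[1], z=czyx[0])
        return PredictResult(
            mask=mask,
            centre=centre,
            prob_map=onp.asarray(detach(out.prob_map)),
            roi_corner=out.crops.corners[0],
        )
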