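"""Conventional 3-D U-Net comparator.

A standard encoder-decoder with skip connections that decodes the *full*
volume.  Its convolutional blocks are identical to the ROI-attention
network's (3-D conv + instance norm + ReLU, strided-conv downsampling) but
without the CBAM, non-local, or ROI machinery, so comparisons between the
two isolate the ROI-attention mechanism itself.  Per U-Net convention each
encoder and decoder stage applies two convolutions.
"""

from __future__ import annotations

from dataclasses import dataclass

import autograd.numpy as np
import numpy as onp

from ..volumes import LabelMask, Volume3D
from . import ops
from .ops import conv3d, detach, instance_norm, relu, softmax_channels, upsample2
from .roi_unet import pad_to_divisible

__all__ = ["BaselineConfig", "BaselineUNet"]


@dataclass(frozen=True)
class BaselineConfig:
    levels: int = 4
    channels: tuple[int, ...] = (32, 64, 128, 256)
    num_classes: int = 2

    def __post_init__(self) -> None:
        if self.levels < 2:
            raise ValueError("levels must be >= 2")
        if len(self.channels) != self.levels:
            raise ValueError("channels must list one width per level")

    @classmethod
    def test_scale(cls) -> "BaselineConfig":
        return cls(levels=4, channels=(8, 16, 32, 64))


class BaselineUNet:
    def __init__(self, cfg: BaselineConfig | None = None):
        self.cfg = cfg or BaselineConfig()

    def init_params(self, seed: int = 0) -> dict:
        rng = onp.random.default_rng(seed)
        cfg = self.cfg
        p: dict[str, onp.ndarray] = {}

        def conv_block(name, cin, cout, k=3):
            p[f"{name}_w"] = ops.he_init(rng, (cout, cin, k, k, k), cin * k**3)
            p[f"{name}_b"] = onp.zeros(cout)
            p[f"{name}_g"] = onp.ones(cout)
            p[f"{name}_bb"] = onp.zeros(cout)

        chans = cfg.channels
        conv_block("enc0_a", 1, chans[0])
        conv_block("enc0_b", chans[0], chans[0])
        for k in range(1, cfg.levels):
            conv_block(f"enc{k}_a", chans[k], chans[k])
            conv_block(f"enc{k}_b", chans[k], chans[k])
        for k in range(cfg.levels - 1):
            conv_block(f"down{k}", chans[k], chans[k + 1])
        for k in range(cfg.levels - 2, -1, -1):
            conv_block(f"dec{k}_a", chans[k + 1] + chans[k], chans[k])
            conv_block(f"dec{k}_b", chans[k], chans[k])
        p["head_w"] = ops.he_init(rng, (cfg.num_classes, chans[0], 1, 1, 1), chans[0])
        p["head_b"] = onp.zeros(cfg.num_classes)
        return p

    @staticmethod
    def parameter_count(params: dict) -> int:
        return int(sum(onp.asarray(v).size for v in params.values()))

    def _conv_block(self, p, name, x, stride=1):
        x = conv3d(x, p[f"{name}_w"], p[f"{name}_b"], stride=stride)
        x = instance_norm(x, p[f"{name}_g"], p[f"{name}_bb"])
        return relu(x)

    def forward(self, params: dict, vol):
        """Per-voxel class scores at input resolution, ``(num_classes, D, H, W)``."""
        cfg = self.cfg
        data = vol.data if isinstance(vol, Volume3D) else vol
        shape = tuple(int(s) for s in data.shape[-3:])
        div = 2 ** (cfg.levels - 1)
        if any(s % div for s in shape):
            raise ValueError(
                f"input shape {shape} is not divisible by 2^(levels-1)={div}; "
                "pad the volume (see pad_to_divisible) before the forward pass"
            )
        x = np.reshape(data, (1,) + shape)
        mu = np.mean(x)
        sd = np.sqrt(np.mean((x - mu) ** 2)) + 1e-8
        x = (x - mu) / sd

        skips = []
        for k in range(cfg.levels - 1):
            x = self._conv_block(params, f"enc{k}_a", x)
            x = self._conv_block(params, f"enc{k}_b", x)
            skips.append(x)
            x = self._conv_block(params, f"down{k}", x, stride=2)
        x = self._conv_block(params, f"enc{cfg.levels - 1}_a", x)
        x = self._conv_block(params, f"enc{cfg.levels - 1}_b", x)
        for k in range(cfg.levels - 2, -1, -1):
            x = np.concatenate([upsample2(x), skips[k]], axis=0)
            x = self._conv_block(params, f"dec{k}_a", x)
            x = self._conv_block(params, f"dec{k}_b", x)
        return conv3d(x, params["head_w"], params["head_b"])

    def predict(self, params: dict, vol: Volume3D):
        div = 2 ** (self.cfg.levels - 1)
        data = onp.asarray(vol.data, dtype=float)
        padded, lo = pad_to_divisible(data, div)
        scores = onp.asarray(detach(self.forward(params, padded)))
        mask_padded = onp.argmax(scores, axis=0).astype(onp.uint8)
        sl = tuple(slice(lo[a], lo[a] + data.shape[a]) for a in range(3))
        return LabelMask(mask_padded[sl], vol.spacing)

    def foreground_prob(self, params: dict, vol):
        """Differentiable full-volume foreground probability."""
        return softmax_channels(self.forward(params, vol))[1]
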