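"""Seeded training and evaluation loops for both architectures.

Training is full-gradient Adam over minibatches of whole phantom volumes.
Everything is driven by numpy generators seeded from the config, and all
operations are deterministic, so a run is exactly reproducible from its
seed.  Per-step loss components are logged as structured records suitable
for a CSV training log.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as onp
from autograd import value_and_grad
from autograd.misc.flatten import flatten

from .losses import LossBreakdown, LossWeights, dice_loss, localization_loss, total_loss, weighted_dice_loss
from .nn.baseline import BaselineUNet
from .nn.ops import detach
from .nn.roi_unet import RoiAttentionUNet, RoiCentre
from .phantom import PhantomSample
from .volumes import LabelMask, dice_coefficient

import autograd.numpy as np

__all__ = [
    "TrainConfig",
    "EvalReport",
    "train",
    "evaluate",
    "sample_loss",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings (Adam)."""

    epochs: int = 30
    batch_size: int = 2
    learning_rate: float = 1e-3
    seed: int = 0
    loss_weights: LossWeights = field(default_factory=LossWeights)

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be > 0")
        if self.batch_size < 1:
            raise ValueError("batch size must be >= 1")


@dataclass
class EvalReport:
    """Held-out evaluation: per-sample Dice and (if available) centre error."""

    region: str
    per_sample_dice: list[float]
    per_sample_centre_error: list[float] | None = None

    @property
    def mean_dice(self) -> float:
        return float(onp.mean(self.per_sample_dice))

    @property
    def mean_centre_error(self) -> float | None:
        if self.per_sample_centre_error is None:
            return None
        return float(onp.mean(self.per_sample_centre_error))


def _onehot(mask_data: onp.ndarray) -> onp.ndarray:
    m = onp.asarray(mask_data, dtype=float)
    return onp.stack([1.0 - m, m], axis=0)


def sample_loss(model, params, sample: PhantomSample, weights: LossWeights) -> LossBreakdown:
    """Composite loss for one phantom under either architecture.

    For the ROI-attention net the ROI Dice target is the ground-truth mask
    cropped at the *predicted* centre (the crop index is detached, so centre
    gradients flow only through the localization term).  The baseline U-Net
    is trained with the full-volume weighted Dice only.
    """
    truth = sample.truth_mask.data
    if isinstance(model, RoiAttentionUNet):
        out = model.forward(params, sample.fat.data)
        tx, ty, tz = sample.truth_centre_normalized
        L_loc = localization_loss(out.centre, RoiCentre(x=tx, y=ty, z=tz))
        z, y, x = out.crops.corners[0]
        r = model.cfg.roi_sizes[0]
        roi_target = truth[z : z + r, y : y + r, x : x + r]
        L_roi = dice_loss(out.roi_fg_prob, roi_target)
        fg = out.full_fg_prob
        pred = np.concatenate([(1.0 - fg)[None], fg[None]], axis=0)
        L_seg = weighted_dice_loss(pred, _onehot(truth))
        return total_loss(L_seg, L_roi, L_loc, weights)
    if isinstance(model, BaselineUNet):
        fg = model.foreground_prob(params, sample.fat.data)
        pred = np.concatenate([(1.0 - fg)[None], fg[None]], axis=0)
        L_seg = weighted_dice_loss(pred, _onehot(truth))
        return total_loss(L_seg, 0.0, 0.0, weights)
    raise TypeError(f"unsupported model type: {type(model).__name__}")


def train(model, samples: list[PhantomSample], cfg: TrainConfig | None = None):
    """Train ``model`` on phantoms; returns ``(params, log)``.

    ``log`` is a list of per-step dicts with keys
    ``step, epoch, L_total, L_seg, L_roi, L_loc``.

    Raises
    ------
    RuntimeError
        If the loss becomes NaN; the message reports the last finite step.
    """
    cfg = cfg or TrainConfig()
    if not samples:
        raise ValueError("training set is empty")
    shapes = {s.fat.shape for s in samples}
    if len(shapes) != 1:
        raise ValueError(f"all training samples must share one shape, got {shapes}")

    params = model.init_params(cfg.seed)
    flat, unflatten = flatten(params)
    aux: dict = {}

    def batch_loss(flat_vec, batch):
        p = unflatten(flat_vec)
        tot = 0.0
        comps = onp.zeros(3)
        for s in batch:
            br = sample_loss(model, p, s, cfg.loss_weights)
            tot = tot + br.L_total
            comps += [float(detach(br.L_seg)), float(detach(br.L_roi)), float(detach(br.L_loc))]
        aux["seg"], aux["roi"], aux["loc"] = comps / len(batch)
        return tot / len(batch)

    vag = value_and_grad(batch_loss)
    m = onp.zeros_like(flat)
    v = onp.zeros_like(flat)
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    rng = onp.random.default_rng(cfg.seed + 1)
    log: list[dict] = []
    step = 0
    for epoch in range(cfg.epochs):
        order = rng.permutation(len(samples))
        for start in range(0, len(samples), cfg.batch_size):
            batch = [samples[i] for i in order[start : start + cfg.batch_size]]
            value, grad = vag(flat, batch)
            if not onp.isfinite(value):
                last = log[-1] if log else None
                raise RuntimeError(
                    f"non-finite loss at step {step}; last finite step: {last}"
                )
            step += 1
            m = beta1 * m + (1 - beta1) * grad
            v = beta2 * v + (1 - beta2) * grad**2
            mhat = m / (1 - beta1**step)
            vhat = v / (1 - beta2**step)
            flat = flat - cfg.learning_rate * mhat / (onp.sqrt(vhat) + eps)
            log.append(
                {
                    "step": step,
                    "epoch": epoch,
                    "L_total": float(value),
                    "L_seg": float(aux["seg"]),
                    "L_roi": float(aux["roi"]),
                    "L_loc": float(aux["loc"]),
                }
            )
    return unflatten(flat), log


def evaluate(model, params, samples: list[PhantomSample]) -> EvalReport:
    """Dice (and centre error, for the ROI net) on held-out phantoms."""
    if not samples:
        raise ValueError("validation set is empty")
    dices: list[float] = []
    centre_errors: list[float] = []
    has_centre = isinstance(model, RoiAttentionUNet)
    for s in samples:
        res = model.predict(params, s.fat)
        mask = res.mask if hasattr(res, "mask") else res
        dices.append(dice_coefficient(mask, s.truth_mask))
        if has_centre:
            pred = onp.array(res.centre.as_xyz())
            true = onp.array(s.truth_centre_normalized)
            centre_errors.append(float(onp.linalg.norm(pred - true)))
    region = samples[0].config.region.value
    return EvalReport(
        region=region,
        per_sample_dice=dices,
        per_sample_centre_error=centre_errors if has_centre else None,
    )


def save_checkpoint(params: dict, path) -> None:
    """Save a parameter dict to an ``.npz`` checkpoint."""
    onp.savez(path, **{k: onp.asarray(v) for k, v in params.items()})


def load_checkpoint(path) -> dict:
    with onp.load(path) as data:
        return {k: data[k] for k in data.files}
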