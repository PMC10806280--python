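"""The composite training objective ``L = Lseg + λ1·LROI + λ2·Lloc``.

* ``Lseg`` — a class-weighted Dice loss over the *full* volume, with each
  class weighted by the reciprocal of its target voxel count.  This keeps
  the tiny foreground from being swamped by the background class.
* ``LROI`` — the conventional (unweighted) Dice loss over the detected ROI.
* ``Lloc`` — squared Euclidean distance between the predicted and true ROI
  centres in normalized [-1, 1] coordinates.

All functions accept either plain numpy arrays or autograd-traced values,
so the same code serves training and testing.

Numerical conventions (documented so independent oracles can match them
exactly): Dice smoothing ``eps = 1e-6`` is added to numerator and
denominator; reciprocal class weights use counts inflated by one voxel
(``w_c ∝ 1 / (n_c + 1)``) so an absent class keeps a finite weight, and the
weights are normalized to sum to one.
"""

from __future__ import annotations

from dataclasses import dataclass

import autograd.numpy as np
import numpy as onp

from .nn.ops import detach

__all__ = [
    "DICE_EPS",
    "LossWeights",
    "LossBreakdown",
    "dice_loss",
    "weighted_dice_loss",
    "localization_loss",
    "total_loss",
]

DICE_EPS = 1e-6


@dataclass(frozen=True)
class LossWeights:
    """Mixing weights λ1 (ROI Dice) and λ2 (centre localization)."""

    lambda1: float = 1.0
    lambda2: float = 1.0

    def __post_init__(self) -> None:
        for name, v in (("lambda1", self.lambda1), ("lambda2", self.lambda2)):
            if not onp.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v}")


@dataclass
class LossBreakdown:
    L_total: float
    L_seg: float
    L_roi: float
    L_loc: float


def _check_shapes(pred, target) -> None:
    ps = detach(pred).shape
    ts = onp.asarray(detach(target)).shape
    if ps != ts:
        raise ValueError(f"prediction shape {ps} does not match target shape {ts}")


def dice_loss(pred, target, eps: float = DICE_EPS):
    """Soft Dice loss ``1 - (2·Σ p·t + eps) / (Σ p + Σ t + eps)`` in [0, 1]."""
    _check_shapes(pred, target)
    target = onp.asarray(detach(target), dtype=float)
    inter = np.sum(pred * target)
    denom = np.sum(pred) + onp.sum(target)
    return 1.0 - (2.0 * inter + eps) / (denom + eps)


def weighted_dice_loss(pred, target_onehot, eps: float = DICE_EPS):
    """Reciprocal-voxel-count weighted multi-class Dice loss.

    ``pred`` holds per-class probabilities ``(C, ...)`` summing to 1 over
    classes at every voxel; ``target_onehot`` is the one-hot target of the
    same shape.
    """
    _check_shapes(pred, target_onehot)
    target = onp.asarray(detach(target_onehot), dtype=float)
    if target.shape[0] < 2:
        raise ValueError("weighted Dice needs >= 2 classes on axis 0")
    col_sums = onp.asarray(detach(pred)).sum(axis=0)
    if onp.max(onp.abs(col_sums - 1.0)) > 1e-3:
        raise ValueError("per-voxel class probabilities must sum to 1 (tol 1e-3)")
    counts = target.reshape(target.shape[0], -1).sum(axis=1)
    w = 1.0 / (counts + 1.0)
    w = w / w.sum()
    loss = 0.0
    for c in range(target.shape[0]):
        loss = loss + w[c] * dice_loss(pred[c], target[c], eps=eps)
    return loss


def _centre_components(centre):
    if hasattr(centre, "as_zyx"):
        return centre.as_zyx()
    seq = tuple(centre)
    if len(seq) != 3:
        raise ValueError("a centre must have exactly 3 components")
    return seq


def localization_loss(pred_centre, true_centre):
    """Squared Euclidean distance between two centres in normalized coords."""
    pa = _centre_components(pred_centre)
    pb = _centre_components(true_centre)
    out = 0.0
    for a, b in zip(pa, pb):
        out = out + (a - b) ** 2
    return out


def total_loss(L_seg, L_roi, L_loc, weights: LossWeights | None = None) -> LossBreakdown:
    """Combine the three components; raises on a NaN component, naming it."""
    weights = weights or LossWeights()
    parts = {"L_seg": L_seg, "L_roi": L_roi, "L_loc": L_loc}
    for name, v in parts.items():
        if onp.isnan(float(detach(v))):
            raise ValueError(f"loss component {name} is NaN")
    total = L_seg + weights.lambda1 * L_roi + weights.lambda2 * L_loc
    return LossBreakdown(L_total=total, L_seg=L_seg, L_roi=L_roi, L_loc=L_loc)
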