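"""Hybrid region-then-boundary segmentation loss.

The total training loss is

    L_total = L_deepsup + lambda * L_seg,
    L_seg   = (L_focal + L_focal_tversky) + alpha(epoch) * L_HD,

where L_deepsup is a weighted sum of per-head binary cross-entropies
over the four deep-supervision outputs, L_focal is the class-balanced
focal loss, L_focal_tversky is (1 - T)^gamma with T the Tversky index
(beta > alpha penalizes false negatives more), and L_HD is a boundary
penalty that weights the squared prediction error by squared
distance-to-boundary maps of the prediction and ground truth. The HD
weight alpha ramps linearly from 0 by 0.005 per epoch (capped at 1), so
training attends to regions first and boundaries later.

Every function accepts either NumPy arrays or autodiff tensors and
returns a scalar :class:`~tpunet.nn.Tensor` (use ``.item()`` for the
float value). Distance maps are computed outside the gradient path.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from . import nn
from .nn import Tensor, as_tensor

__all__ = [
    "LossConfig",
    "bce",
    "deep_supervision_loss",
    "focal_loss",
    "tversky_index",
    "focal_tversky_loss",
    "distance_map",
    "hd_loss",
    "hd_alpha",
    "seg_loss",
    "total_loss",
]


@dataclass(frozen=True)
class LossConfig:
    """All loss hyperparameters; defaults follow the published setting."""

    lambda_ds: tuple[float, float, float, float] = (0.1, 0.1, 0.1, 0.1)
    alpha_t: float = 0.8  # focal class-balance factor
    gamma_focal: float = 2.0
    alpha_tv: float = 0.3  # Tversky false-positive weight
    beta_tv: float = 0.7  # Tversky false-negative weight
    gamma_tv: float = 2.0
    lambda_seg: float = 0.6  # weight of L_seg in the total loss
    hd_alpha_init: float = 0.0
    hd_alpha_step: float = 0.005
    hd_alpha_max: float = 1.0
    smooth_eps: float = 1e-6

    def __post_init__(self):
        if any(w < 0 for w in self.lambda_ds):
            raise ValueError("deep-supervision weights must be nonnegative")
        if not 0.0 < self.alpha_t < 1.0:
            raise ValueError("alpha_t must lie in (0, 1)")
        if min(self.alpha_tv, self.beta_tv, self.gamma_tv, self.gamma_focal, self.lambda_seg) < 0:
            raise ValueError("loss weights must be nonnegative")
        if self.hd_alpha_init > self.hd_alpha_max:
            raise ValueError("hd_alpha_init must not exceed hd_alpha_max")


_DEFAULT = LossConfig()


def _clamped(p, eps: float) -> Tensor:
    p = as_tensor(p)
    return nn.clip(p, eps, 1.0 - eps)


def _check_shapes(p, g):
    p, g = as_tensor(p), as_tensor(g)
    if p.shape != g.shape:
        raise ValueError(f"prediction shape {p.shape} != target shape {g.shape}")
    return p, g


def bce(p, g, config: LossConfig = _DEFAULT) -> Tensor:
    """Mean per-pixel binary cross-entropy, with p clamped to [eps, 1-eps]."""
    p, g = _check_shapes(p, g)
    p = _clamped(p, config.smooth_eps)
    g = g.detach()
    return nn.tmean(-(g * nn.log(p)) - (1.0 - g) * nn.log(1.0 - p))


def deep_supervision_loss(deepsup_outputs, g, config: LossConfig = _DEFAULT) -> Tensor:
    """Sum of lambda_i-weighted BCEs over the four auxiliary heads."""
    if len(deepsup_outputs) != len(config.lambda_ds):
        raise ValueError(
            f"expected {len(config.lambda_ds)} deep-supervision outputs, got {len(deepsup_outputs)}"
        )
    total = Tensor(0.0)
    for lam, p in zip(config.lambda_ds, deepsup_outputs):
        total = total + lam * bce(p, g, config)
    return total


def focal_loss(p, g, config: LossConfig = _DEFAULT) -> Tensor:
    """Class-balanced focal loss: easy pixels are down-weighted by
    (1-p)^gamma on the target and p^gamma on the background."""
    p, g = _check_shapes(p, g)
    p = _clamped(p, config.smooth_eps)
    g = g.detach()
    at, gamma = config.alpha_t, config.gamma_focal
    pos = at * nn.power(1.0 - p, gamma) * g * nn.log(p)
    neg = (1.0 - at) * nn.power(p, gamma) * (1.0 - g) * nn.log(1.0 - p)
    return nn.tmean(-pos - neg)


def tversky_index(p, g, config: LossConfig = _DEFAULT) -> Tensor:
    """Soft Tversky overlap T = TP / (TP + alpha*FP + beta*FN) in [0, 1]."""
    p, g = _check_shapes(p, g)
    g = g.detach()
    tp = nn.tsum(p * g)
    fp = nn.tsum(p * (1.0 - g))
    fn = nn.tsum((1.0 - p) * g)
    eps = config.smooth_eps
    return (tp + eps) / (tp + config.alpha_tv * fp + config.beta_tv * fn + eps)


def focal_tversky_loss(p, g, config: LossConfig = _DEFAULT) -> Tensor:
    """(1 - T)^gamma: exponent > 1 concentrates the loss on hard cases."""
    t = tversky_index(p, g, config)
    return nn.power(1.0 - t, config.gamma_tv)


def distance_map(mask: np.ndarray) -> np.ndarray:
    """Unsigned Euclidean distance to the mask boundary, in pixels.

    Foreground pixels get the distance to the nearest background pixel
    and background pixels the distance to the nearest foreground pixel.
    All-zero and all-one masks have no boundary and map to all zeros.
    """
    mask = np.asarray(mask)
    binary = mask > 0.5
    if binary.all() or not binary.any():
        return np.zeros(mask.shape, dtype=np.float64)
    inside = ndimage.distance_transform_edt(binary)
    outside = ndimage.distance_transform_edt(~binary)
    return inside + outside  # one of the two is zero at every pixel


def _batch_distance_map(masks: np.ndarray) -> np.ndarray:
    """distance_map applied over leading batch/channel axes of a 4-D array."""
    masks = np.asarray(masks)
    if masks.ndim <= 2:
        return distance_map(masks)
    flat = masks.reshape(-1, masks.shape[-2], masks.shape[-1])
    return np.stack([distance_map(m) for m in flat]).reshape(masks.shape)


def hd_loss(p, g) -> Tensor:
    """Boundary-aware penalty: mean of (g - p)^2 * (d(p)^2 + d(g)^2).

    d(p) is the distance map of the 0.5-thresholded prediction; both
    distance maps are constants with respect to the gradient, which
    flows only through the squared error term.
    """
    p, g = _check_shapes(p, g)
    g = g.detach()
    dp = _batch_distance_map(p.data > 0.5)
    dg = _batch_distance_map(g.data > 0.5)
    weight = Tensor(dp * dp + dg * dg)
    return nn.tmean(nn.power(g - p, 2.0) * weight)


def hd_alpha(epoch: int, config: LossConfig = _DEFAULT) -> float:
    """Linear boundary-loss ramp: min(init + epoch*step, max)."""
    if epoch < 0:
        raise ValueError("epoch must be nonnegative")
    return min(config.hd_alpha_init + epoch * config.hd_alpha_step, config.hd_alpha_max)


def seg_loss(p, g, epoch: int, config: LossConfig = _DEFAULT) -> Tensor:
    """Region terms plus the scheduled boundary term for the final head."""
    loss = focal_loss(p, g, config) + focal_tversky_loss(p, g, config)
    alpha = hd_alpha(epoch, config)
    if alpha > 0:
        loss = loss + alpha * hd_loss(p, g)
    return loss


def total_loss(output, g, epoch: int, config: LossConfig = _DEFAULT) -> Tensor:
    """L_deepsup + lambda_seg * L_seg for a full network output."""
    ds = deep_supervision_loss(output.deepsup, g, config)
    return ds + config.lambda_seg * seg_loss(output.prediction, g, epoch, config)
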