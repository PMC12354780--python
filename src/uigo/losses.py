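"""Segmentation training losses.

The training objective is a tri-composite loss

    L = 0.27 * FL + 0.69 * DL + 0.04 * HD

combining focal loss (class imbalance), soft Dice loss (region overlap) and a
differentiable Hausdorff surrogate (boundary placement).  Tversky and
focal-Tversky variants are provided for ablation.

All losses accept either plain numpy arrays (returning a float) or autodiff
:class:`~uigo.autodiff.Tensor` predictions (returning a Tensor on the tape, so
they can drive training).  Targets are always binary arrays.

The exact symmetric Hausdorff distance is not differentiable; the surrogate
penalizes predicted mass by its squared distance transform to the target and
missed target mass by its squared distance to the thresholded prediction,
normalized by the squared image diagonal so values stay in [0, 1].  Exact
Hausdorff lives in :mod:`uigo.metrics` and is used for reporting only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .autodiff import Tensor

logger = logging.getLogger("uigo.losses")

__all__ = [
    "FocalParams",
    "LossWeights",
    "TverskyParams",
    "focal_loss",
    "dice_loss",
    "hausdorff_surrogate",
    "composite_loss",
    "tversky_loss",
    "focal_tversky_loss",
]

_EPS_CLIP = 1e-7


@dataclass(frozen=True)
class FocalParams:
    """alpha weights the foreground class (1-alpha the background); gamma >= 0
    is the focusing exponent.  gamma=0, alpha=0.5 is scaled cross-entropy."""
    alpha: float = 0.25
    gamma: float = 2.0

    def __post_init__(self):
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha must be in [0,1], got {self.alpha}")
        if self.gamma < 0:
            raise ValueError(f"gamma must be >= 0, got {self.gamma}")


@dataclass(frozen=True)
class LossWeights:
    w_focal: float = 0.27
    w_dice: float = 0.69
    w_hausdorff: float = 0.04

    def __post_init__(self):
        if min(self.w_focal, self.w_dice, self.w_hausdorff) < 0:
            raise ValueError("loss weights must be non-negative")


@dataclass(frozen=True)
class TverskyParams:
    alpha: float = 0.7      # false-positive weight
    beta: float = 0.3       # false-negative weight
    gamma_ft: float = 0.75  # focal exponent (focal-Tversky only)


def _as_tensor(pred) -> tuple[Tensor, bool]:
    if isinstance(pred, Tensor):
        return pred, True
    return Tensor(np.asarray(pred, dtype=np.float64)), False


def _ret(value: Tensor, is_tensor: bool):
    return value if is_tensor else float(value.data)


def focal_loss(pred, target: np.ndarray, p: FocalParams = FocalParams()):
    """Mean over pixels of -alpha_t (1 - p_t)^gamma log(p_t)."""
    pred_t, is_tensor = _as_tensor(pred)
    target = np.asarray(target, dtype=np.float64)
    if pred_t.data.shape != target.shape:
        raise ValueError(f"shape mismatch {pred_t.data.shape} vs {target.shape}")
    if np.any(pred_t.data <= 0.0) or np.any(pred_t.data >= 1.0):
        logger.debug("focal_loss: clipping predictions to [%g, %g]", _EPS_CLIP, 1 - _EPS_CLIP)
    pc = pred_t.clamp(_EPS_CLIP, 1.0 - _EPS_CLIP)
    p_t = pc * target + (1.0 - pc) * (1.0 - target)
    alpha_t = p.alpha * target + (1.0 - p.alpha) * (1.0 - target)
    mod = (1.0 - p_t).pow(p.gamma) if p.gamma != 0 else 1.0
    loss = (-(Tensor(alpha_t) * mod * p_t.log())).mean()
    return _ret(loss, is_tensor)


def dice_loss(pred, target: np.ndarray, smooth: float = 1.0,
              per_sample: bool = False):
    """1 - (2 sum(p*t) + smooth) / (sum(p) + sum(t) + smooth).

    With ``per_sample`` the sums run over all but the first axis and the loss
    is averaged across the batch; a per-slice Dice gives small structures a
    far larger gradient share than one global sum over the batch, which is
    what the training loop uses.
    """
    pred_t, is_tensor = _as_tensor(pred)
    target = np.asarray(target, dtype=np.float64)
    if pred_t.data.shape != target.shape:
        raise ValueError(f"shape mismatch {pred_t.data.shape} vs {target.shape}")
    if per_sample and pred_t.data.ndim > 1:
        axes = tuple(range(1, pred_t.data.ndim))
        inter = (pred_t * target).sum(axis=axes)
        denom = pred_t.sum(axis=axes) + Tensor(target.sum(axis=axes))
        loss = (1.0 - (2.0 * inter + smooth) / (denom + smooth)).mean()
        return _ret(loss, is_tensor)
    inter = (pred_t * target).sum()
    denom = pred_t.sum() + float(target.sum())
    if smooth == 0.0 and float(denom.data) == 0.0:
        return _ret(Tensor(0.0), is_tensor)  # both empty: perfect by convention
    loss = 1.0 - (2.0 * inter + smooth) / (denom + smooth)
    return _ret(loss, is_tensor)


def _edt_to(mask: np.ndarray, diag: float) -> np.ndarray:
    """Distance of every pixel to the mask's foreground; diag if mask empty.

    Inputs with leading batch/channel axes are transformed slice-by-slice over
    the trailing two (spatial) dimensions.
    """
    mask = mask.astype(bool)
    if mask.ndim == 2:
        if not mask.any():
            return np.full(mask.shape, diag)
        return ndimage.distance_transform_edt(~mask)
    flat = mask.reshape(-1, *mask.shape[-2:])
    out = np.stack([_edt_to(m, diag) for m in flat])
    return out.reshape(mask.shape)


def hausdorff_surrogate(pred, target: np.ndarray, threshold: float = 0.5):
    """Differentiable boundary penalty normalized to [0, 1].

    mean( pred * d(target)^2 + (1 - pred) * target * d(pred_bin)^2 ) / diag^2
    where d(.) is the Euclidean distance transform to the given set and
    pred_bin thresholds the prediction at 0.5 (constant w.r.t. the tape).
    """
    pred_t, is_tensor = _as_tensor(pred)
    target = np.asarray(target).astype(bool)
    if pred_t.data.shape != target.shape:
        raise ValueError(f"shape mismatch {pred_t.data.shape} vs {target.shape}")
    h, w = target.shape[-2], target.shape[-1]
    diag = float(np.hypot(h, w))
    pred_bin = pred_t.data >= threshold
    if not target.any() and not pred_bin.any():
        logger.debug("hausdorff_surrogate: both masks empty, returning 0")
        return _ret(Tensor(0.0), is_tensor)
    dt_target = _edt_to(target, diag)
    dt_pred = _edt_to(pred_bin, diag)
    tgt = target.astype(np.float64)
    penalty = pred_t * Tensor(dt_target ** 2) + (1.0 - pred_t) * Tensor(tgt * dt_pred ** 2)
    loss = penalty.mean() * (1.0 / diag ** 2)
    return _ret(loss, is_tensor)


def composite_loss(pred, target: np.ndarray, w: LossWeights = LossWeights(),
                   fp: FocalParams = FocalParams(), smooth: float = 1.0,
                   per_sample: bool = False):
    """Weighted sum of the three components; returns (total, components dict).

    Components are returned as floats for logging regardless of input type.
    ``per_sample`` is forwarded to the Dice term (batched training).
    """
    pred_t, is_tensor = _as_tensor(pred)
    fl = focal_loss(pred_t, target, fp)
    dl = dice_loss(pred_t, target, smooth, per_sample=per_sample)
    hd = hausdorff_surrogate(pred_t, target)
    total = w.w_focal * fl + w.w_dice * dl + w.w_hausdorff * hd
    components = {"focal": float(fl.data), "dice": float(dl.data),
                  "hausdorff": float(hd.data)}
    return _ret(total, is_tensor), components


def _soft_counts(pred_t: Tensor, target: np.ndarray):
    tp = (pred_t * target).sum()
    fp_ = (pred_t * (1.0 - target)).sum()
    fn_ = ((1.0 - pred_t) * target).sum()
    return tp, fp_, fn_


def tversky_loss(pred, target: np.ndarray, p: TverskyParams = TverskyParams(),
                 smooth: float = 0.5):
    """1 - TP/(TP + alpha FP + beta FN) on soft counts.

    The default smoothing (0.5 in numerator and denominator) makes
    alpha = beta = 0.5 coincide exactly with :func:`dice_loss` at its default
    smoothing of 1.0.
    """
    pred_t, is_tensor = _as_tensor(pred)
    target = np.asarray(target, dtype=np.float64)
    if pred_t.data.shape != target.shape:
        raise ValueError(f"shape mismatch {pred_t.data.shape} vs {target.shape}")
    tp, fp_, fn_ = _soft_counts(pred_t, target)
    denom = tp + p.alpha * fp_ + p.beta * fn_
    if smooth == 0.0 and float(denom.data) == 0.0:
        return _ret(Tensor(0.0), is_tensor)
    ti = (tp + smooth) / (denom + smooth)
    return _ret(1.0 - ti, is_tensor)


def focal_tversky_loss(pred, target: np.ndarray, p: TverskyParams = TverskyParams(),
                       smooth: float = 0.5):
    """(1 - TI)^gamma_ft."""
    pred_t, is_tensor = _as_tensor(pred)
    base = tversky_loss(pred_t, target, p, smooth)
    loss = base.pow(p.gamma_ft)
    return _ret(loss, is_tensor)
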