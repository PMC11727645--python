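"""Training losses for heavily imbalanced vessel segmentation.

The headline loss is the Weighted Asymmetric Focal Tversky (WAFT) loss,

    L = alpha * (1 - TI_bg) + beta * (1 - TI_fg)^(1 - gamma)

where TI is the soft Tversky index

    TI = (TP + eps) / (TP + delta*FN + (1-delta)*FP + eps)

computed from soft confusion masses on sigmoid probabilities; the
background index uses (1 - prob, 1 - gt).  ``delta > 0.5`` weights missed
vessels (FN) above spurious vessels (FP), ``alpha/beta`` trade the
background term against the foreground term (defaults 0.2 / 0.8), and the
focal exponent ``1 - gamma`` (gamma in [0, 1)) magnifies the foreground
term when it is small, i.e. keeps pressure on hard, nearly-solved images.

Standard comparison losses — soft Dice, pixel cross-entropy, plain Tversky,
focal, and the asymmetric focal Tversky (AFT, the unweighted
foreground-only special case of WAFT) — share the same soft-count plumbing.

All functions accept either numpy arrays (returning a float) or autodiff
tensors (returning a differentiable scalar tensor).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, as_tensor, clip, log, where_positive

__all__ = [
    "SoftConfusion",
    "WAFTParams",
    "soft_confusion",
    "tversky_index",
    "waft_loss",
    "dice_loss",
    "cross_entropy_loss",
    "tversky_loss",
    "focal_loss",
    "aft_loss",
    "get_loss",
]


@dataclass
class WAFTParams:
    """Knobs of the WAFT loss.

    alpha, beta : background / foreground class weights (should sum to 1).
    delta       : FN-vs-FP trade-off inside the Tversky index, in [0, 1];
                  above 0.5 prioritises not missing vessels.
    gamma       : focal parameter in [0, 1); the foreground term is raised
                  to the power 1 - gamma.
    epsilon     : stabiliser preventing division by zero on empty classes.
    """

    alpha: float = 0.2
    beta: float = 0.8
    delta: float = 0.7
    gamma: float = 0.25
    epsilon: float = 1e-6

    def __post_init__(self):
        if not 0.0 <= self.delta <= 1.0:
            raise ValueError(f"delta must be in [0,1], got {self.delta}")
        if self.gamma < 0:
            raise ValueError(f"gamma must be >= 0, got {self.gamma}")
        if self.epsilon <= 0:
            raise ValueError(f"epsilon must be > 0, got {self.epsilon}")
        if abs(self.alpha + self.beta - 1.0) > 1e-9:
            warnings.warn(
                f"alpha + beta = {self.alpha + self.beta:g} != 1; the class "
                "weights are conventionally a convex combination",
                stacklevel=3,
            )


class SoftConfusion:
    """Soft TP/FN/FP pixel masses for one class (values may be tensors)."""

    __slots__ = ("tp", "fn", "fp")

    def __init__(self, tp, fn, fp):
        self.tp, self.fn, self.fp = tp, fn, fp


def _prepare(prob, gt):
    wrapped = not isinstance(prob, Tensor)
    prob = as_tensor(prob)
    gt_arr = np.asarray(gt.data if isinstance(gt, Tensor) else gt, dtype=np.float64)
    if prob.shape != gt_arr.shape:
        raise ValueError(f"shape mismatch: prob {prob.shape} vs gt {gt_arr.shape}")
    if prob.data.min() < 0 or prob.data.max() > 1:
        raise ValueError("prob must lie in [0, 1]")
    return prob, gt_arr, wrapped


def _ret(value: Tensor, wrapped: bool):
    return value.item() if wrapped else value


def soft_confusion(prob, gt, cls: str = "fg") -> SoftConfusion:
    """Soft confusion masses: tp = sum(p*g), fn = sum((1-p)*g), fp = sum(p*(1-g)).

    ``cls='bg'`` computes the same counts for the background class, i.e. on
    (1 - prob, 1 - gt).
    """
    prob, gt_arr, _ = _prepare(prob, gt)
    if cls == "bg":
        prob = 1.0 - prob
        gt_arr = 1.0 - gt_arr
    elif cls != "fg":
        raise ValueError(f"cls must be 'fg' or 'bg', got {cls!r}")
    return SoftConfusion(
        tp=(prob * gt_arr).sum(),
        fn=((1.0 - prob) * gt_arr).sum(),
        fp=(prob * (1.0 - gt_arr)).sum(),
    )


def tversky_index(c: SoftConfusion, delta: float = 0.7, epsilon: float = 1e-6):
    """(TP + eps) / (TP + delta*FN + (1-delta)*FP + eps), in (0, 1]."""
    if not 0.0 <= delta <= 1.0:
        raise ValueError(f"delta must be in [0,1], got {delta}")
    return (c.tp + epsilon) / (c.tp + delta * c.fn + (1.0 - delta) * c.fp + epsilon)


def waft_loss(prob, gt, params: WAFTParams | None = None):
    """Weighted asymmetric focal Tversky loss (see module docstring).

    Zero at a perfect hard prediction; bounded by alpha + beta for
    gamma <= 1.  The focal power is applied to the epsilon-floored
    foreground complement so the gradient stays finite as TI_fg -> 1.
    """
    p = params or WAFTParams()
    prob, gt_arr, wrapped = _prepare(prob, gt)
    ti_bg = tversky_index(soft_confusion(prob, gt_arr, "bg"), p.delta, p.epsilon)
    ti_fg = tversky_index(soft_confusion(prob, gt_arr, "fg"), p.delta, p.epsilon)
    comp = 1.0 - ti_fg
    # floor before the fractional power: d/dx x^(1-gamma) diverges at 0
    comp = where_positive(comp.data > p.epsilon, comp, as_tensor(p.epsilon))
    loss = p.alpha * (1.0 - ti_bg) + p.beta * comp ** (1.0 - p.gamma)
    return _ret(loss, wrapped)


def dice_loss(prob, gt, epsilon: float = 1e-6):
    """1 - soft Dice = 1 - 2TP / (2TP + FN + FP)."""
    prob, gt_arr, wrapped = _prepare(prob, gt)
    c = soft_confusion(prob, gt_arr, "fg")
    soft_dice = (2.0 * c.tp + epsilon) / (2.0 * c.tp + c.fn + c.fp + epsilon)
    return _ret(1.0 - soft_dice, wrapped)


def cross_entropy_loss(prob, gt, clip_eps: float = 1e-7):
    """Mean binary cross-entropy with probability clipping."""
    prob, gt_arr, wrapped = _prepare(prob, gt)
    pc = clip(prob, clip_eps, 1.0 - clip_eps)
    ll = gt_arr * log(pc) + (1.0 - gt_arr) * log(1.0 - pc)
    return _ret(-ll.mean(), wrapped)


def tversky_loss(prob, gt, delta: float = 0.7, epsilon: float = 1e-6):
    """1 - TI_fg; at delta = 0.5 this equals the soft Dice loss of the
    same counts up to the epsilon convention."""
    prob, gt_arr, wrapped = _prepare(prob, gt)
    ti = tversky_index(soft_confusion(prob, gt_arr, "fg"), delta, epsilon)
    return _ret(1.0 - ti, wrapped)


def focal_loss(prob, gt, gamma_focal: float = 2.0, clip_eps: float = 1e-7):
    """Unweighted pixel focal loss: mean of -(1 - p_t)^gamma * log(p_t)."""
    prob, gt_arr, wrapped = _prepare(prob, gt)
    pc = clip(prob, clip_eps, 1.0 - clip_eps)
    pt = where_positive(gt_arr > 0.5, pc, 1.0 - pc)
    loss = -((1.0 - pt) ** gamma_focal * log(pt)).mean()
    return _ret(loss, wrapped)


def aft_loss(prob, gt, params: WAFTParams | None = None):
    """Asymmetric focal Tversky loss: the foreground term of WAFT alone,
    (1 - TI_fg)^(1 - gamma) — WAFT with alpha = 0, beta = 1."""
    p = params or WAFTParams()
    prob, gt_arr, wrapped = _prepare(prob, gt)
    ti_fg = tversky_index(soft_confusion(prob, gt_arr, "fg"), p.delta, p.epsilon)
    comp = 1.0 - ti_fg
    comp = where_positive(comp.data > p.epsilon, comp, as_tensor(p.epsilon))
    return _ret(comp ** (1.0 - p.gamma), wrapped)


_LOSSES = {
    "waft": waft_loss,
    "aft": aft_loss,
    "dice": lambda prob, gt, params=None: dice_loss(prob, gt),
    "cross_entropy": lambda prob, gt, params=None: cross_entropy_loss(prob, gt),
    "tversky": lambda prob, gt, params=None: tversky_loss(
        prob, gt, delta=(params.delta if params else 0.7)),
    "focal": lambda prob, gt, params=None: focal_loss(prob, gt),
}


def get_loss(name: str):
    """Look up a loss by config name: waft, aft, dice, cross_entropy,
    tversky, focal.  Each has signature (prob, gt, params=None)."""
    try:
        return _LOSSES[name]
    except KeyError:
        raise ValueError(f"unknown loss {name!r}; choose from {sorted(_LOSSES)}") from None
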