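"""Segmentation quality metrics for thin, connected vessel networks.

Pixel-overlap metrics (Dice, Jaccard, balanced accuracy, recall) come from
the per-pixel confusion table.  Because overlap alone is blind to
fragmentation of the vascular tree, the suite also includes the
morphology-aware CAL metric of Gegundez-Arias et al. — the product of a
Connectivity, an Area and a Length factor, each in [0, 1] — and the largest
connected component (LCC) ratio, which compares skeleton lengths of the
biggest connected structure in prediction and ground truth.

Conventions for degenerate inputs are explicit because the formulas are
undefined there: exact agreement on an all-background image scores 1 (a
correct "nothing to segment" answer), while an empty ground-truth mask where
a formula divides by a ground-truth count raises ``ValueError``.

Connected components use 8-connectivity throughout — vessels are thin,
often diagonal structures that 4-connectivity would artificially fragment.
The "disc of radius 1" structuring element is the 4-connected cross (the
Euclidean disc of radius 1 on the pixel grid, ``skimage.morphology.disk(1)``);
pass a different footprint if a 3x3 square is preferred.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.measure import label
from skimage.morphology import disk, skeletonize

__all__ = [
    "ConfusionCounts",
    "CALComponents",
    "SegmentationMetrics",
    "confusion_counts",
    "dice",
    "jaccard",
    "bacc",
    "recall",
    "connectivity_C",
    "area_A",
    "length_L",
    "cal",
    "cal_components",
    "lcc",
    "evaluate",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """Per-pixel 2x2 contingency table between prediction and ground truth."""

    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class CALComponents:
    """The connectivity/area/length factors and the dilation radii used."""

    c: float
    a: float
    l: float
    alpha_radius: int = 1
    beta_radius: int = 1

    @property
    def cal(self) -> float:
        return 100.0 * self.c * self.a * self.l


@dataclass(frozen=True)
class SegmentationMetrics:
    """The full per-image metric suite.  dice..rec in [0,1]; cal, lcc in [0,100]."""

    dice: float
    jac: float
    bacc: float
    rec: float
    cal: float
    lcc: float

    def as_dict(self) -> dict:
        return {
            "dice": self.dice, "jac": self.jac, "bacc": self.bacc,
            "rec": self.rec, "cal": self.cal, "lcc": self.lcc,
        }


def _as_binary(mask, name: str) -> np.ndarray:
    arr = np.asarray(mask)
    if arr.dtype != bool:
        vals = np.unique(arr)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValueError(f"{name} must be binary, found values {vals[:5]}")
        arr = arr.astype(bool)
    return arr


def _check_pair(pred, gt):
    pred = _as_binary(pred, "pred")
    gt = _as_binary(gt, "gt")
    if pred.shape != gt.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs gt {gt.shape}")
    return pred, gt


def confusion_counts(pred, gt) -> ConfusionCounts:
    """Count TP/FP/FN/TN pixels between two binary masks of equal shape."""
    pred, gt = _check_pair(pred, gt)
    tp = int(np.count_nonzero(pred & gt))
    fp = int(np.count_nonzero(pred & ~gt))
    fn = int(np.count_nonzero(~pred & gt))
    tn = int(np.count_nonzero(~pred & ~gt))
    return ConfusionCounts(tp, fp, fn, tn)


def dice(c: ConfusionCounts) -> float:
    """Dice coefficient 2TP / (2TP + FP + FN); 1 on all-background agreement."""
    denom = 2 * c.tp + c.fp + c.fn
    return 1.0 if denom == 0 else 2.0 * c.tp / denom


def jaccard(c: ConfusionCounts) -> float:
    """Jaccard index TP / (TP + FP + FN); 1 on all-background agreement."""
    denom = c.tp + c.fp + c.fn
    return 1.0 if denom == 0 else c.tp / denom


def recall(c: ConfusionCounts) -> float:
    """Sensitivity TP / (TP + FN); 1 when the ground truth has no positives."""
    denom = c.tp + c.fn
    return 1.0 if denom == 0 else c.tp / denom


def bacc(c: ConfusionCounts) -> float:
    """Balanced accuracy: mean of sensitivity and specificity.

    If one class is absent from the ground truth, only the defined half is
    reported (the other term has an empty denominator).
    """
    pos, neg = c.tp + c.fn, c.tn + c.fp
    if pos == 0 and neg == 0:
        raise ValueError("empty image")
    terms = []
    if pos:
        terms.append(c.tp / pos)
    if neg:
        terms.append(c.tn / neg)
    return float(np.mean(terms))


def _n_components(mask: np.ndarray) -> int:
    return int(label(mask, connectivity=2).max())


def connectivity_C(pred, gt) -> float:
    """Connectivity factor: penalises fragmentation of the vessel network.

    ``C = 1 - min(1, |#comp(gt) - #comp(pred)| / #pixels(gt))``.
    """
    pred, gt = _check_pair(pred, gt)
    n_gt_px = int(np.count_nonzero(gt))
    if n_gt_px == 0:
        raise ValueError("connectivity_C: ground-truth mask is empty")
    diff = abs(_n_components(gt) - _n_components(pred))
    return 1.0 - min(1.0, diff / n_gt_px)


def _dilate(mask: np.ndarray, radius: int) -> np.ndarray:
    if radius == 0:
        return mask
    return ndimage.binary_dilation(mask, structure=disk(radius))


def area_A(pred, gt, alpha_radius: int = 1) -> float:
    """Area factor: overlap with a dilation tolerance of ``alpha_radius`` px.

    ``A = |(dil(pred) & gt) | (pred & dil(gt))| / |pred | gt|``.
    """
    pred, gt = _check_pair(pred, gt)
    union = pred | gt
    n_union = int(np.count_nonzero(union))
    if n_union == 0:
        raise ValueError("area_A: both masks empty")
    numer = (_dilate(pred, alpha_radius) & gt) | (pred & _dilate(gt, alpha_radius))
    return int(np.count_nonzero(numer)) / n_union


def length_L(pred, gt, beta_radius: int = 1) -> float:
    """Length factor: coincidence of skeletons with ``beta_radius`` tolerance.

    ``L = |(skel(pred) & dil(gt)) | (dil(pred) & skel(gt))| /
    |skel(pred) | skel(gt)|``.
    """
    pred, gt = _check_pair(pred, gt)
    sk_pred = skeletonize(pred)
    sk_gt = skeletonize(gt)
    denom_mask = sk_pred | sk_gt
    n_denom = int(np.count_nonzero(denom_mask))
    if n_denom == 0:
        raise ValueError("length_L: both skeletons empty")
    numer = (sk_pred & _dilate(gt, beta_radius)) | (_dilate(pred, beta_radius) & sk_gt)
    return int(np.count_nonzero(numer)) / n_denom


def cal_components(pred, gt, alpha_radius: int = 1, beta_radius: int = 1) -> CALComponents:
    """Compute the C, A, L factors (dilation radii default to 1 px)."""
    return CALComponents(
        c=connectivity_C(pred, gt),
        a=area_A(pred, gt, alpha_radius),
        l=length_L(pred, gt, beta_radius),
        alpha_radius=alpha_radius,
        beta_radius=beta_radius,
    )


def cal(pred, gt, alpha_radius: int = 1, beta_radius: int = 1) -> float:
    """CAL = 100 * C * A * L, in [0, 100]; 100 is a perfect segmentation.

    An empty prediction against a nonempty ground truth scores 0 (the area
    factor vanishes).
    """
    pred, gt = _check_pair(pred, gt)
    if not pred.any():
        if not gt.any():
            raise ValueError("cal: ground-truth mask is empty")
        return 0.0
    return cal_components(pred, gt, alpha_radius, beta_radius).cal


def _largest_skeleton_component(mask: np.ndarray) -> int:
    """Pixel length of the largest 8-connected component of the skeleton."""
    sk = skeletonize(mask)
    labels = label(sk, connectivity=2)
    if labels.max() == 0:
        return 0
    return int(np.bincount(labels.ravel())[1:].max())


def lcc(pred, gt) -> float:
    """Largest-connected-component ratio on the 0-100 scale.

    Skeletonise both masks, take the pixel length of the largest connected
    skeleton component of each, and report
    ``100 * (1 - min(1, |len_pred - len_gt| / len_gt))``.  Both too-short
    (fragmented) and too-long (over-connected) predictions are penalised.
    """
    pred, gt = _check_pair(pred, gt)
    len_gt = _largest_skeleton_component(gt)
    if len_gt == 0:
        raise ValueError("lcc: ground-truth skeleton is empty")
    len_pred = _largest_skeleton_component(pred)
    return 100.0 * (1.0 - min(1.0, abs(len_pred - len_gt) / len_gt))


def evaluate(pred_prob, gt, threshold: float = 0.5,
             alpha_radius: int = 1, beta_radius: int = 1) -> SegmentationMetrics:
    """Binarise a probability map and compute the full metric suite."""
    prob = np.asarray(pred_prob, dtype=float)
    if prob.min() < 0 or prob.max() > 1:
        raise ValueError("pred_prob must lie in [0, 1]")
    pred = prob >= threshold
    gt = _as_binary(gt, "gt")
    c = confusion_counts(pred, gt)
    return SegmentationMetrics(
        dice=dice(c),
        jac=jaccard(c),
        bacc=bacc(c),
        rec=recall(c),
        cal=cal(pred, gt, alpha_radius, beta_radius),
        lcc=lcc(pred, gt),
    )
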