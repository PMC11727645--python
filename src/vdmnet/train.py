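"""Training loop: Adam, polynomial LR decay, flip/rotate augmentation.

The recipe follows the common small-data segmentation setup: batch size 1,
Adam (beta1 = 0.9, i.e. the "momentum" of the optimiser) with L2 weight
decay 0.001, a polynomial learning-rate schedule
``lr = base_lr * (1 - iter/max_iter)^power`` stepped per iteration, and
augmentation by independent 50% horizontal/vertical flips plus a uniform
rotation in [-10, 10] degrees (bilinear for the image, nearest for the
mask, which is re-binarised afterwards).

Everything is driven by a single integer seed: sample order, augmentation
draws and parameter initialisation are all reproducible, so two runs with
the same config produce identical loss trajectories.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .autodiff import no_grad
from .losses import WAFTParams, get_loss
from .metrics import confusion_counts, dice as dice_metric
from .model import VDMNet, predict
from .synthetic import ImageSample

__all__ = ["TrainConfig", "Adam", "poly_lr", "augment", "train"]


@dataclass
class TrainConfig:
    base_lr: float = 1e-3
    power: float = 0.9
    max_epochs: int = 100
    batch_size: int = 1
    weight_decay: float = 1e-3
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    hflip: bool = True
    vflip: bool = True
    rotation_deg: tuple[float, float] = (-10.0, 10.0)
    seed: int = 0
    loss: str = "waft"
    loss_params: WAFTParams = field(default_factory=WAFTParams)
    threshold: float = 0.5

    def validate(self) -> None:
        if self.base_lr <= 0:
            raise ValueError("config key 'base_lr' must be > 0")
        if self.power <= 0:
            raise ValueError("config key 'power' must be > 0")
        if self.max_epochs < 1:
            raise ValueError("config key 'max_epochs' must be >= 1")
        lo, hi = self.rotation_deg
        if lo < -10.0 or hi > 10.0 or lo > hi:
            raise ValueError("config key 'rotation_deg' must lie within [-10, 10]")


def poly_lr(base_lr: float, iteration: int, max_iter: int, power: float) -> float:
    """Polynomial decay ``base_lr * (1 - iter/max_iter)^power``.

    Equals ``base_lr`` at iteration 0 and 0 at ``max_iter``; strictly
    decreasing in between for ``power > 0``.
    """
    if not 0 <= iteration <= max_iter:
        raise ValueError(f"iteration {iteration} outside [0, {max_iter}]")
    if power <= 0:
        raise ValueError(f"power must be > 0, got {power}")
    return base_lr * (1.0 - iteration / max_iter) ** power


class Adam:
    """Adam with L2 weight decay added to the gradient."""

    def __init__(self, params, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8, weight_decay: float = 0.0):
        self.params = list(params)
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.weight_decay = weight_decay
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self, lr: float) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1**self.t
        bias2 = 1.0 - b2**self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad + self.weight_decay * p.data
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g**2
            p.data -= lr * (self.m[i] / bias1) / (np.sqrt(self.v[i] / bias2) + self.eps)


def augment(sample: ImageSample, rng: np.random.Generator | int,
            hflip: bool = True, vflip: bool = True,
            rotation_deg: tuple[float, float] = (-10.0, 10.0)) -> ImageSample:
    """Random flips and a small rotation, applied identically to image and mask.

    The mask is rotated with nearest-neighbour interpolation and re-binarised,
    so it stays strictly {0, 1}.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    image, mask = sample.image.copy(), sample.mask.copy()
    if hflip and rng.random() < 0.5:
        image, mask = image[:, ::-1], mask[:, ::-1]
    if vflip and rng.random() < 0.5:
        image, mask = image[::-1], mask[::-1]
    angle = rng.uniform(*rotation_deg)
    if angle != 0.0:
        image = ndimage.rotate(image, angle, reshape=False, order=1, mode="reflect")
        mask = ndimage.rotate(mask.astype(np.float64), angle, reshape=False,
                              order=0, mode="constant")
    image = np.clip(image, 0.0, 1.0)
    mask = (mask > 0.5).astype(np.uint8)
    return ImageSample(image=np.ascontiguousarray(image),
                       mask=np.ascontiguousarray(mask), id=sample.id)


def _val_dice(model: VDMNet, samples, threshold: float) -> float:
    scores = []
    for s in samples:
        _, mask = predict(model, s.image, threshold)
        scores.append(dice_metric(confusion_counts(mask, s.mask)))
    return float(np.mean(scores))


def train(model: VDMNet, dataset, cfg: TrainConfig | None = None,
          val_dataset=None, log=None) -> dict:
    """Train ``model`` on a list of image/mask samples.

    Returns a history dict with per-epoch mean training loss, per-epoch
    validation Dice (when a validation set is given), the best state dict
    (selected on validation Dice, else on training loss) and the iteration
    count.  A non-finite loss aborts with diagnostics.
    """
    cfg = cfg or TrainConfig()
    cfg.validate()
    if not dataset:
        raise ValueError("training dataset is empty")
    loss_fn = get_loss(cfg.loss)
    rng = np.random.default_rng(cfg.seed)
    optimizer = Adam(model.parameters(), cfg.adam_beta1, cfg.adam_beta2,
                     weight_decay=cfg.weight_decay)
    max_iter = cfg.max_epochs * len(dataset)

    history = {"train_loss": [], "val_dice": [], "lr": [],
               "best_state": None, "best_score": -np.inf, "iterations": 0}
    iteration = 0
    for epoch in range(cfg.max_epochs):
        model.train()
        order = rng.permutation(len(dataset))
        losses = []
        for idx in order:
            sample = augment(dataset[idx], rng, cfg.hflip, cfg.vflip, cfg.rotation_deg)
            lr = poly_lr(cfg.base_lr, iteration, max_iter, cfg.power)
            prob = model(sample.image[None, None])
            loss = loss_fn(prob.reshape(prob.shape[2], prob.shape[3]),
                           sample.mask.astype(np.float64), cfg.loss_params)
            value = loss.item()
            if not np.isfinite(value):
                raise RuntimeError(
                    f"non-finite loss {value} at epoch {epoch} iteration {iteration} "
                    f"(sample {sample.id!r}, lr {lr:g})")
            optimizer.zero_grad()
            loss.backward()
            optimizer.step(lr)
            losses.append(value)
            history["lr"].append(lr)
            iteration += 1
        epoch_loss = float(np.mean(losses))
        history["train_loss"].append(epoch_loss)

        if val_dataset:
            with no_grad():
                score = _val_dice(model, val_dataset, cfg.threshold)
            history["val_dice"].append(score)
        else:
            score = -epoch_loss
        if score > history["best_score"]:
            history["best_score"] = score
            history["best_state"] = model.state_dict()
        if log is not None:
            log(f"epoch {epoch + 1}/{cfg.max_epochs} loss {epoch_loss:.4f}"
                + (f" val_dice {history['val_dice'][-1]:.4f}" if val_dataset else ""))
    history["iterations"] = iteration
    return history
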