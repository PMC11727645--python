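"""Synthetic OCTA-like angiogram generator.

Real en-face OCTA angiograms of the retinal microvasculature show sparse,
thin, curved, bifurcating and crossing bright vessels over a speckled,
low-contrast background.  This module generates image/mask pairs with that
statistical structure so the whole segmentation pipeline can be exercised
and tested without any dataset download.

Vessel trees are biased random walks seeded on the image border and headed
into the interior: at each unit step the heading receives a bounded random
turn (curvature), a disc whose radius tapers from the maximum to the
minimum vessel radius is stamped, and with a small per-step probability the
walk bifurcates into a thinner child branch.  Rendering assigns vessels an
intensity ``contrast`` above a fixed background level, applies
multiplicative speckle ``(1 + noise_level * N(0,1))``, Gaussian-blurs, and
clips to [0, 1].

Everything is a pure function of its parameter record (including the
seed): the same parameters always produce bit-identical output.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, replace
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from scipy import ndimage
from skimage.draw import disk as draw_disk

__all__ = [
    "VesselTreeParams",
    "RenderParams",
    "ImageSample",
    "generate_vessel_mask",
    "render_octa_image",
    "generate_sample",
    "generate_dataset",
]

BACKGROUND_LEVEL = 0.25  # intensity floor of the avascular background
SPECKLE_GRAIN_SIGMA = 1.5  # correlation length (px) of the speckle field


@dataclass(frozen=True)
class VesselTreeParams:
    """Geometry of the simulated vascular tree.

    width_range is the (min, max) vessel *radius* in pixels; trunks start
    at the maximum and taper to the minimum.  curvature is the largest
    per-step heading change in radians.  crossing=False stops a walk when
    it would overlap a previously drawn tree.
    """

    seed: int = 0
    height: int = 128
    width: int = 128
    n_trees: int = 3
    branch_prob: float = 0.08
    width_range: tuple[int, int] = (1, 4)
    curvature: float = 0.25
    crossing: bool = True

    def __post_init__(self):
        if self.height < 64 or self.width < 64:
            raise ValueError(
                f"image size {self.height}x{self.width} too small (min 64x64)")
        if not 0.0 <= self.branch_prob <= 1.0:
            raise ValueError(f"branch_prob must be in [0,1], got {self.branch_prob}")
        lo, hi = self.width_range
        if lo < 1 or hi < lo:
            raise ValueError(f"invalid width_range {self.width_range}")
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")


@dataclass(frozen=True)
class RenderParams:
    """Appearance of the rendered angiogram."""

    seed: int = 0
    noise_level: float = 0.2
    contrast: float = 0.5
    blur_sigma: float = 0.7

    def __post_init__(self):
        if not 0.0 <= self.noise_level < 1.0:
            raise ValueError(f"noise_level must be in [0,1), got {self.noise_level}")
        if not 0.0 <= self.contrast <= 1.0:
            raise ValueError(f"contrast must be in [0,1], got {self.contrast}")
        if self.blur_sigma < 0:
            raise ValueError(f"blur_sigma must be >= 0, got {self.blur_sigma}")


@dataclass
class ImageSample:
    """One grayscale angiogram with its binary vessel mask.

    ``mask`` may be None for prediction-only samples loaded without ground
    truth.
    """

    image: np.ndarray
    mask: np.ndarray | None
    id: str = ""

    def __post_init__(self):
        if self.mask is None:
            return
        if self.image.shape != self.mask.shape:
            raise ValueError(
                f"image {self.image.shape} and mask {self.mask.shape} differ")
        if not np.all(np.isin(np.unique(self.mask), (0, 1))):
            raise ValueError("mask must be binary {0,1}")


def _stamp(mask: np.ndarray, y: float, x: float, radius: int) -> None:
    if radius <= 1:
        yi = min(max(int(round(y)), 0), mask.shape[0] - 1)
        xi = min(max(int(round(x)), 0), mask.shape[1] - 1)
        mask[yi, xi] = True
        return
    rr, cc = draw_disk((y, x), radius, shape=mask.shape)
    mask[rr, cc] = True


_MAX_SEGMENTS = 32  # per tree, keeps bifurcation cascades bounded


def _walk_tree(mask: np.ndarray, others: np.ndarray, rng: np.random.Generator,
               p: VesselTreeParams) -> None:
    h, w = p.height, p.width
    rmin, rmax = p.width_range
    max_steps = int(0.85 * max(h, w))

    side = rng.integers(4)
    t = rng.uniform(0.15, 0.85)
    if side == 0:
        y, x, heading = 0.0, t * w, np.pi / 2
    elif side == 1:
        y, x, heading = h - 1.0, t * w, -np.pi / 2
    elif side == 2:
        y, x, heading = t * h, 0.0, 0.0
    else:
        y, x, heading = t * h, w - 1.0, np.pi
    heading += rng.uniform(-0.5, 0.5)

    # stack of (y, x, heading, radius, steps_left); children are pushed on
    # bifurcation and walked after their parent finishes
    stack = [(y, x, heading, float(rmax), max_steps)]
    segments = 0
    while stack and segments < _MAX_SEGMENTS:
        y, x, heading, r0, steps = stack.pop()
        segments += 1
        for step in range(steps):
            frac = 1.0 - step / max_steps
            radius = int(round(rmin + (r0 - rmin) * max(frac, 0.0)))
            if not (0 <= y < h and 0 <= x < w):
                break
            if not p.crossing and others[int(round(y)), int(round(x))]:
                break
            _stamp(mask, y, x, max(radius, rmin))
            heading += rng.uniform(-p.curvature, p.curvature)
            # bifurcate only while the vessel is still thicker than terminal
            if radius > rmin and rng.random() < p.branch_prob:
                split = rng.uniform(0.35, 0.9) * (1 if rng.random() < 0.5 else -1)
                stack.append((y, x, heading + split,
                              max(r0 * 0.7, float(rmin)),
                              int((steps - step) * 0.7)))
            y += np.sin(heading)
            x += np.cos(heading)


def generate_vessel_mask(params: VesselTreeParams) -> np.ndarray:
    """Draw a binary vessel-tree mask; deterministic in ``params.seed``."""
    rng = np.random.default_rng(params.seed)
    mask = np.zeros((params.height, params.width), dtype=bool)
    for _ in range(params.n_trees):
        drawn = mask.copy()
        _walk_tree(mask, drawn, rng, params)
    return mask.astype(np.uint8)


def render_octa_image(mask: np.ndarray, params: RenderParams) -> np.ndarray:
    """Render an angiogram-like intensity image in [0, 1] from a mask."""
    mask = np.asarray(mask)
    if not np.all(np.isin(np.unique(mask), (0, 1))):
        raise ValueError("mask must be binary")
    rng = np.random.default_rng(params.seed)
    image = BACKGROUND_LEVEL + params.contrast * mask.astype(np.float64)
    if params.noise_level > 0:
        # OCTA speckle is spatially correlated: low-pass a white field and
        # renormalise to unit variance before the multiplicative mix
        grain = ndimage.gaussian_filter(rng.standard_normal(mask.shape),
                                        SPECKLE_GRAIN_SIGMA)
        grain /= grain.std()
        image = image * (1.0 + params.noise_level * grain)
    if params.blur_sigma > 0:
        image = ndimage.gaussian_filter(image, params.blur_sigma)
    return np.clip(image, 0.0, 1.0)


def generate_sample(tree: VesselTreeParams, render: RenderParams,
                    sample_id: str = "") -> ImageSample:
    mask = generate_vessel_mask(tree)
    image = render_octa_image(mask, render)
    return ImageSample(image=image, mask=mask, id=sample_id)


def generate_dataset(n: int, out_dir, tree: VesselTreeParams | None = None,
                     render: RenderParams | None = None) -> list[ImageSample]:
    """Write ``n`` image/mask PNG pairs plus a manifest to ``out_dir``.

    Sample ``i`` uses seed ``base_seed + i`` for both the tree and the
    rendering, so extending ``n`` never changes earlier samples.  Layout:
    ``out_dir/images/<id>.png``, ``out_dir/masks/<id>.png`` (8-bit, masks
    {0, 255}) and ``out_dir/manifest.json``.
    """
    tree = tree or VesselTreeParams()
    render = render or RenderParams()
    out_dir = Path(out_dir)
    (out_dir / "images").mkdir(parents=True, exist_ok=True)
    (out_dir / "masks").mkdir(parents=True, exist_ok=True)

    samples = []
    ids = []
    for i in range(n):
        sid = f"sample_{i:04d}"
        sample = generate_sample(
            replace(tree, seed=tree.seed + i),
            replace(render, seed=render.seed + i),
            sample_id=sid,
        )
        iio.imwrite(out_dir / "images" / f"{sid}.png",
                    np.round(sample.image * 255).astype(np.uint8))
        iio.imwrite(out_dir / "masks" / f"{sid}.png",
                    (sample.mask * 255).astype(np.uint8))
        samples.append(sample)
        ids.append(sid)

    manifest = {
        "ids": ids,
        "provenance": {"tree": asdict(tree), "render": asdict(render)},
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return samples
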