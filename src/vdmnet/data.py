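"""Dataset and result I/O.

A dataset directory holds ``images/<id>.png``, ``masks/<id>.png`` and an
optional ``manifest.json`` (id list, optional train/val/test split,
generator provenance).  Images are 8-bit grayscale scaled to [0, 1] on
read; masks are binarised at > 127.  The same layout is produced by the
synthetic generator and accepted for external data dropped in by the user.

Outputs: probability maps as 16-bit PNG (value = round(p * 65535)), binary
masks as 8-bit {0, 255} PNG, per-image metrics as CSV and their means as
JSON, plus a YAML snapshot of the run configuration.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml

from .synthetic import ImageSample

__all__ = ["DatasetManifest", "load_dataset", "load_image", "load_mask",
           "write_outputs"]

PROB_SCALE = 65535  # 16-bit probability quantisation


@dataclass
class DatasetManifest:
    ids: list[str]
    split: dict[str, str] = field(default_factory=dict)  # id -> train/val/test
    provenance: dict = field(default_factory=lambda: {"source": "external"})

    def subset(self, name: str) -> list[str]:
        return [i for i in self.ids if self.split.get(i, "train") == name]


def load_image(path) -> np.ndarray:
    path = Path(path)
    try:
        raw = iio.imread(path)
    except Exception as exc:  # noqa: BLE001 - surface the offending path
        raise ValueError(f"unreadable image {path}: {exc}") from exc
    if raw.ndim == 3:
        raw = raw[..., :3].mean(axis=-1)
    info = np.iinfo(raw.dtype) if np.issubdtype(raw.dtype, np.integer) else None
    scale = info.max if info else 1.0
    return raw.astype(np.float64) / scale


def load_mask(path) -> np.ndarray:
    path = Path(path)
    try:
        raw = iio.imread(path)
    except Exception as exc:  # noqa: BLE001
        raise ValueError(f"unreadable mask {path}: {exc}") from exc
    if raw.ndim == 3:
        raw = raw[..., :3].mean(axis=-1)
    return (raw > 127).astype(np.uint8)


def load_dataset(directory, require_masks: bool = True):
    """Load a dataset directory; returns ``(manifest, samples)``.

    Missing masks raise when ``require_masks``; image/mask shape mismatches
    always raise, naming the offending path and both shapes.
    """
    directory = Path(directory)
    images_dir = directory / "images"
    if not images_dir.is_dir():
        raise ValueError(f"no images/ directory under {directory}")

    manifest_path = directory / "manifest.json"
    if manifest_path.exists():
        raw = json.loads(manifest_path.read_text())
        manifest = DatasetManifest(
            ids=list(raw["ids"]),
            split=dict(raw.get("split", {})),
            provenance=dict(raw.get("provenance", {"source": "external"})),
        )
    else:
        manifest = DatasetManifest(
            ids=sorted(p.stem for p in images_dir.glob("*.png")))

    seen = set()
    for sid in manifest.ids:
        if sid in seen:
            raise ValueError(f"duplicate sample id {sid!r} in manifest")
        seen.add(sid)

    samples = []
    for sid in manifest.ids:
        img_path = images_dir / f"{sid}.png"
        if not img_path.exists():
            raise ValueError(f"manifest id {sid!r} has no image at {img_path}")
        image = load_image(img_path)
        mask_path = directory / "masks" / f"{sid}.png"
        mask = None
        if mask_path.exists():
            mask = load_mask(mask_path)
            if mask.shape != image.shape:
                raise ValueError(
                    f"shape mismatch for {sid!r}: image {image.shape} at {img_path}, "
                    f"mask {mask.shape} at {mask_path}")
        elif require_masks:
            raise ValueError(f"missing mask for {sid!r} (expected {mask_path})")
        samples.append(ImageSample(image=image, mask=mask, id=sid))
    return manifest, samples


def write_outputs(out_dir, ids, probs=None, masks=None, metrics=None,
                  config: dict | None = None) -> None:
    """Write probability maps, masks, metrics and a config snapshot.

    ``metrics`` is a list of per-image dicts (aligned with ``ids``); the
    CSV holds one row per image and ``metrics.json`` the column means.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if probs is not None:
        prob_dir = out_dir / "probabilities"
        prob_dir.mkdir(exist_ok=True)
        for sid, prob in zip(ids, probs):
            arr = np.round(np.asarray(prob) * PROB_SCALE).astype(np.uint16)
            iio.imwrite(prob_dir / f"{sid}.png", arr)
    if masks is not None:
        mask_dir = out_dir / "masks"
        mask_dir.mkdir(exist_ok=True)
        for sid, mask in zip(ids, masks):
            iio.imwrite(mask_dir / f"{sid}.png",
                        (np.asarray(mask, dtype=np.uint8) * 255))
    if metrics is not None:
        frame = pd.DataFrame(metrics, index=pd.Index(ids, name="id"))
        frame.to_csv(out_dir / "metrics.csv", float_format="%.6f")
        means = {k: float(v) for k, v in frame.mean().items()}
        (out_dir / "metrics.json").write_text(json.dumps(means, indent=2))
    if config is not None:
        (out_dir / "config.yaml").write_text(yaml.safe_dump(config, sort_keys=True))
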