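"""YAML configuration: one file with model/train/loss sections.

Every architecture and training default is a named key; unknown keys are
rejected so typos fail loudly.  ``loss:`` selects the loss by name and
``loss_params:`` feeds :class:`~vdmnet.losses.WAFTParams`.
"""

from __future__ import annotations

from dataclasses import fields
from pathlib import Path

import yaml

from .losses import WAFTParams
from .model import ModelConfig
from .train import TrainConfig

__all__ = ["load_config", "config_to_dict"]


def _build(cls, section: dict, name: str):
    valid = {f.name for f in fields(cls)}
    unknown = set(section) - valid
    if unknown:
        raise ValueError(f"unknown {name} config keys: {sorted(unknown)}")
    coerced = dict(section)
    for f in fields(cls):
        if f.name in coerced and isinstance(coerced[f.name], list):
            coerced[f.name] = tuple(coerced[f.name])
    return cls(**coerced)


def load_config(path=None, overrides: dict | None = None):
    """Load (ModelConfig, TrainConfig) from YAML; missing keys use defaults."""
    raw = {}
    if path is not None:
        raw = yaml.safe_load(Path(path).read_text()) or {}
    if overrides:
        for section, values in overrides.items():
            raw.setdefault(section, {}).update(values)
    model_cfg = _build(ModelConfig, raw.get("model", {}), "model")
    train_section = dict(raw.get("train", {}))
    loss_name = raw.get("loss", train_section.pop("loss", "waft"))
    loss_params = _build(WAFTParams, raw.get("loss_params", {}), "loss_params")
    train_cfg = _build(TrainConfig, train_section, "train")
    train_cfg.loss = loss_name
    train_cfg.loss_params = loss_params
    model_cfg.validate()
    train_cfg.validate()
    return model_cfg, train_cfg


def config_to_dict(model_cfg: ModelConfig, train_cfg: TrainConfig) -> dict:
    from dataclasses import asdict

    train = asdict(train_cfg)
    loss_params = train.pop("loss_params")
    loss = train.pop("loss")
    train["rotation_deg"] = list(train["rotation_deg"])
    return {
        "model": asdict(model_cfg),
        "train": train,
        "loss": loss,
        "loss_params": loss_params,
    }
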