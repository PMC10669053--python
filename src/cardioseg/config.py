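"""YAML experiment configuration: one file covering phantom generation,
augmentation, loss and training hyperparameters.

Layout (all sections optional; omitted keys fall back to the dataclass
defaults)::

    phantom:
      shape: [16, 96, 96]
      spacing: [5.0, 1.0, 1.0]
      seed: 0
    augment:
      p_hflip: 0.5
      max_translate_frac: 0.05
      scale_range: [0.95, 1.05]
    loss:
      alpha: 1.0
      gamma: 1.0
    train:
      learning_rate: 1.0e-4
      batch_size: 12
      max_epochs: 300
      grouping: group2
"""

from __future__ import annotations

import os
from dataclasses import asdict

import yaml

from .cascade import TrainConfig
from .losses import LossConfig
from .phantom import PhantomSpec
from .preprocess import AugmentSpec

__all__ = ["load_config", "save_config", "build_train_config", "build_phantom_spec"]


def load_config(path: str | os.PathLike) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config root must be a mapping")
    return cfg


def _tupled(d: dict, *keys: str) -> dict:
    out = dict(d)
    for k in keys:
        if k in out and isinstance(out[k], list):
            out[k] = tuple(out[k])
    return out


def build_phantom_spec(cfg: dict) -> PhantomSpec:
    section = _tupled(cfg.get("phantom", {}), "shape", "spacing")
    return PhantomSpec(**section)


def build_train_config(cfg: dict) -> TrainConfig:
    train = _tupled(dict(cfg.get("train", {})), "split")
    if "loss" in cfg:
        train["loss"] = LossConfig(**cfg["loss"])
    if "augment" in cfg:
        aug = cfg["augment"]
        train["augment"] = (
            AugmentSpec(**_tupled(aug, "scale_range")) if aug is not None else None
        )
    return TrainConfig(**train)


def save_config(cfg_or_train, path: str | os.PathLike) -> None:
    """Write a config mapping (or a TrainConfig snapshot) as YAML."""
    if isinstance(cfg_or_train, TrainConfig):
        train = asdict(cfg_or_train)
        loss = train.pop("loss")
        augment = train.pop("augment")
        payload = {"train": train, "loss": loss, "augment": augment}
    else:
        payload = cfg_or_train
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)
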