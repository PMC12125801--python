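"""YAML config parsing into typed specs."""

from __future__ import annotations

from pathlib import Path

import yaml

from .arch import ModelConfig
from .loss import DiceLossSpec
from .phantom import PhantomSpec
from .pipeline import TrainConfig
from .preprocess import AugmentationSpec, WindowSpec

__all__ = ["load_train_config", "train_config_from_dict"]


def _window_from_dict(d: dict) -> WindowSpec:
    return WindowSpec(center=d.get("center", WindowSpec().center),
                      width=d.get("width", WindowSpec().width))


def train_config_from_dict(cfg: dict) -> TrainConfig:
    """Build a TrainConfig from a nested dict (YAML layout).

    Recognized top-level keys: ``model``, ``loss``, ``preprocess`` (with
    ``window`` and ``augmentation`` sub-keys), ``train`` and ``data``.
    """
    kwargs: dict = {}
    if "model" in cfg:
        kwargs["model"] = ModelConfig.from_dict(cfg["model"])
    if "loss" in cfg:
        kwargs["loss"] = DiceLossSpec(**cfg["loss"])
    pre = cfg.get("preprocess", {})
    if "window" in pre:
        kwargs["window"] = _window_from_dict(pre["window"])
    if "augmentation" in pre:
        aug = pre["augmentation"]
        if aug is None:
            kwargs["augmentation"] = None
        else:
            if "zoom_range" in aug:
                aug = {**aug, "zoom_range": tuple(aug["zoom_range"])}
            kwargs["augmentation"] = AugmentationSpec(**aug)
    train = cfg.get("train", {})
    for key in ("optimizer", "learning_rate", "batch_size", "epochs",
                "early_stopping_patience", "seed"):
        if key in train:
            kwargs[key] = train[key]
    data = cfg.get("data", {})
    if "dir" in data:
        kwargs["data_dir"] = data["dir"]
    if "n_phantoms" in data:
        kwargs["n_phantoms"] = data["n_phantoms"]
    if "phantom" in data:
        kwargs["phantom_base"] = PhantomSpec.from_dict(
            {**PhantomSpec().to_dict(), **data["phantom"]}
        )
    if "jitter" in data:
        kwargs["phantom_jitter"] = {
            k: tuple(v) for k, v in data["jitter"].items()
        }
    return TrainConfig(**kwargs)


def load_train_config(path: str | Path) -> TrainConfig:
    with open(path) as fh:
        return train_config_from_dict(yaml.safe_load(fh) or {})
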