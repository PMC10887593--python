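"""YAML run configuration mapped onto the typed config records.

Example run config::

    augmentation:
      rotation_deg: 15
      shift_frac: 0.1
      shear: 0.2
      zoom_frac: 0.2
      brightness_range: [0.8, 1.2]
      fill_mode: nearest
    preprocess:
      equalize: true
    model:
      backbone_a: {name: tiny_test, stages: 5}
      backbone_b: {name: tiny_test, stages: 5}
      attention: {num_heads: 4, key_dim: 128}
      fusion: {projection_units: 784, reshape_target: [7, 7, 16],
               dropout: 0.23, residual_filters: 256}
      head: {hidden_units: 128, l2_coeff: 6.72e-3, dropout: 0.2377}
      components: {feature_fusion: true, attention_augmentation: true,
                   dynamic_pooling: true, multi_head_attention: true}
    training:
      epochs: 5
      batch_size: 8
      peak_lr: 7.47e-5
      seed: 0
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import yaml

from .attention import AttentionConfig
from .backbones import BackboneSpec
from .fusion import FusionConfig
from .model import ComponentFlags, HeadConfig, ModelConfig
from .preprocessing import AugmentationConfig, PreprocessConfig
from .training import TrainingConfig


@dataclass(frozen=True)
class RunConfig:
    model: ModelConfig
    training: TrainingConfig


def _tupled(mapping: dict, key: str):
    if key in mapping and isinstance(mapping[key], list):
        mapping[key] = tuple(mapping[key])
    return mapping


def load_run_config(path: Path | str) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}

    model_raw = dict(raw.get("model", {}))
    model_kwargs = {}
    if "backbone_a" in model_raw:
        model_kwargs["backbone_a"] = BackboneSpec(**model_raw["backbone_a"])
    if "backbone_b" in model_raw:
        model_kwargs["backbone_b"] = BackboneSpec(**model_raw["backbone_b"])
    if "attention" in model_raw:
        model_kwargs["attention"] = AttentionConfig(**model_raw["attention"])
    if "fusion" in model_raw:
        model_kwargs["fusion"] = FusionConfig(
            **_tupled(dict(model_raw["fusion"]), "reshape_target"))
    if "head" in model_raw:
        model_kwargs["head"] = HeadConfig(**model_raw["head"])
    if "components" in model_raw:
        model_kwargs["components"] = ComponentFlags(**model_raw["components"])
    if "seed" in model_raw:
        model_kwargs["seed"] = model_raw["seed"]

    training_raw = dict(raw.get("training", {}))
    if "augmentation" in raw:
        training_raw["augmentation"] = AugmentationConfig(
            **_tupled(dict(raw["augmentation"]), "brightness_range"))
    if "preprocess" in raw:
        training_raw["preprocess"] = PreprocessConfig(
            **_tupled(dict(raw["preprocess"]), "target_size"))
    return RunConfig(model=ModelConfig(**model_kwargs),
                     training=TrainingConfig(**training_raw))
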