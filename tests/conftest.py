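"""Shared fixtures: synthetic datasets and a trained smoke-test model."""

from __future__ import annotations

import numpy as np
import pytest

from pneumofusion.fixtures import SyntheticConfig, generate_synthetic_dataset
from pneumofusion.model import ModelConfig
from pneumofusion.preprocessing import PreprocessConfig
from pneumofusion.training import TrainingConfig, train_fresh

# The smoke-test study conditions: a balanced 200-images-per-class synthetic
# training set at the network's native 224 px, the published 5-epoch /
# batch-8 warmup-Adam recipe, and a learning rate at the top of the
# published search range (appropriate for training from random init).
SMOKE_FIXTURE = SyntheticConfig(n_per_class=200, image_size=224, seed=3)
SMOKE_TRAINING = TrainingConfig(
    epochs=5, batch_size=8, peak_lr=1e-3, seed=0,
    class_weights={"normal": 1.0, "pneumonia": 1.0},
    preprocess=PreprocessConfig(equalize=False),
)


@pytest.fixture(scope="session")
def small_dataset(tmp_path_factory):
    """25 images per class per split at 64 px — for I/O-level tests."""
    root = tmp_path_factory.mktemp("small")
    cfg = SyntheticConfig(n_per_class=25, image_size=64, seed=1)
    manifests = generate_synthetic_dataset(cfg, root)
    return root, cfg, manifests


@pytest.fixture(scope="session")
def smoke_dataset(tmp_path_factory):
    """The separable training fixture used by the end-to-end smoke tests."""
    root = tmp_path_factory.mktemp("smoke")
    manifests = generate_synthetic_dataset(SMOKE_FIXTURE, root)
    return root, manifests


@pytest.fixture(scope="session")
def smoke_model(smoke_dataset):
    """Full tiny-backbone model trained once under the smoke conditions."""
    _, manifests = smoke_dataset
    model, history = train_fresh(ModelConfig(), manifests["train"],
                                 SMOKE_TRAINING)
    return model, history
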