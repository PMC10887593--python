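"""Backbones, head, full-model assembly, ablations, and the training loop."""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pytest

from pneumofusion.backbones import (BackboneSpec, TinyTestBackbone,
                                    build_backbone, extract_features)
from pneumofusion.fixtures import SyntheticConfig, generate_synthetic_dataset
from pneumofusion.model import (ClassifierHead, ComponentFlags, HeadConfig,
                                ModelConfig, PneumoniaAttentionNet,
                                assemble_model)
from pneumofusion.nn import Tensor
from pneumofusion.preprocessing import PreprocessConfig
from pneumofusion.training import (TrainingConfig, train_fresh,
                                   warmup_schedule, weighted_cross_entropy)

FAST_MODEL = ModelConfig(backbone_a=BackboneSpec("tiny_test", stages=3),
                         backbone_b=BackboneSpec("tiny_test", stages=3))
FAST_PREPROCESS = PreprocessConfig(target_size=(32, 32), equalize=False)


class TestBackbones:
    def test_tiny_geometry(self):
        out = extract_features(
            np.random.default_rng(0).random((2, 32, 32, 3),
                                            dtype=np.float32),
            BackboneSpec("tiny_test"))
        assert out.shape == (2, 4, 4, 16)

    def test_tiny_zero_weights_zero_map(self):
        backbone = build_backbone(BackboneSpec("tiny_test"))
        for conv in backbone.convs:
            conv.weight.data[:] = 0
        out = backbone(Tensor(np.random.default_rng(1).random(
            (1, 16, 16, 3), dtype=np.float32)))
        np.testing.assert_array_equal(out.numpy(), 0.0)

    @pytest.mark.parametrize("name,channels", [("efficientnet_b0", 1280),
                                               ("densenet121", 1024)])
    def test_full_backbone_geometry(self, name, channels):
        """224x224x3 must map to a 7x7 final convolutional feature map."""
        out = extract_features(
            np.random.default_rng(0).random((1, 224, 224, 3),
                                            dtype=np.float32),
            BackboneSpec(name))
        assert out.shape == (1, 7, 7, channels)

    def test_unknown_and_pretrained_rejected(self):
        with pytest.raises(ValueError):
            BackboneSpec("vgg16")
        with pytest.raises(ValueError):
            build_backbone(BackboneSpec("tiny_test", pretrained=True))


class TestHead:
    def test_probabilities_normalized(self):
        rng = np.random.default_rng(0)
        head = ClassifierHead(10, HeadConfig(), rng)
        head.eval()
        from pneumofusion.nn import softmax
        probs = softmax(head(Tensor(rng.standard_normal((5, 10)).astype(
            np.float32)))).numpy()
        assert (probs >= 0).all()
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_zero_weights_symmetric(self):
        head = ClassifierHead(4, HeadConfig(), np.random.default_rng(0))
        head.eval()
        for dense in (head.hidden, head.out):
            dense.weight.data[:] = 0
            dense.bias.data[:] = 0
        from pneumofusion.nn import softmax
        probs = softmax(head(Tensor(np.ones((1, 4), np.float32)))).numpy()
        np.testing.assert_allclose(probs, [[0.5, 0.5]], atol=1e-6)

    def test_l2_penalty_hand_value(self):
        head = ClassifierHead(1, HeadConfig(hidden_units=1, l2_coeff=0.006),
                              np.random.default_rng(0))
        head.hidden.weight.data[:] = 2.0
        assert head.l2_penalty().item() == pytest.approx(0.024, abs=1e-8)


class TestAssembly:
    def test_forward_shape_with_native_input_size(self):
        model = assemble_model(ModelConfig())
        probs = model.predict_proba(np.random.default_rng(0).random(
            (2, 224, 224, 3), dtype=np.float32))
        assert probs.shape == (2, 2)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_all_components_off_is_gap_concat(self):
        model = PneumoniaAttentionNet(
            FAST_MODEL.with_components(ComponentFlags.none()))
        assert not hasattr(model, "fusion")
        assert not hasattr(model, "residual")
        # head consumes the concatenated 16+16 GAP features directly
        assert model.head.hidden.weight.shape[0] == 32
        probs = model.predict_proba(np.random.default_rng(0).random(
            (2, 32, 32, 3), dtype=np.float32))
        assert probs.shape == (2, 2)

    @pytest.mark.parametrize("flag", ["feature_fusion",
                                      "attention_augmentation",
                                      "dynamic_pooling",
                                      "multi_head_attention"])
    def test_removing_any_component_reduces_parameters(self, flag):
        full = PneumoniaAttentionNet(FAST_MODEL)
        ablated = PneumoniaAttentionNet(FAST_MODEL.with_components(
            replace(ComponentFlags(), **{flag: False})))
        assert ablated.n_parameters() < full.n_parameters()


class TestWarmupSchedule:
    def test_reaches_peak_at_end_of_warmup(self):
        assert warmup_schedule(99, 7.47e-5, 100) == pytest.approx(7.47e-5)

    def test_first_step_fraction(self):
        assert warmup_schedule(0, 7.47e-5, 100) == \
            pytest.approx(7.47e-5 / 100)

    def test_zero_warmup_is_constant(self):
        assert warmup_schedule(0, 1e-3, 0) == 1e-3
        assert warmup_schedule(500, 1e-3, 0) == 1e-3


class TestLoss:
    def test_zero_weight_class_contributes_nothing(self):
        rng = np.random.default_rng(0)
        from pneumofusion.nn import softmax
        probs = softmax(Tensor(rng.standard_normal((6, 2)).astype(
            np.float32)))
        targets = np.eye(2, dtype=np.float32)[[0, 1, 0, 1, 0, 1]]
        weights = np.array([2.0, 0.0, 2.0, 0.0, 2.0, 0.0])
        mixed = weighted_cross_entropy(probs, targets, weights).item()
        a_only = weighted_cross_entropy(
            Tensor(probs.data[[0, 2, 4]]), targets[[0, 2, 4]],
            np.ones(3)).item()
        assert mixed == pytest.approx(a_only, rel=1e-6)


@pytest.fixture(scope="module")
def tiny_training_setup(tmp_path_factory):
    root = tmp_path_factory.mktemp("tinytrain")
    manifests = generate_synthetic_dataset(
        SyntheticConfig(n_per_class=8, image_size=32, seed=4), root,
        splits=("train",))
    return manifests["train"]


class TestTrainingLoop:
    def test_training_is_deterministic(self, tiny_training_setup):
        cfg = TrainingConfig(epochs=1, batch_size=8, peak_lr=1e-3, seed=9,
                             preprocess=FAST_PREPROCESS)
        _, h1 = train_fresh(FAST_MODEL, tiny_training_setup, cfg)
        _, h2 = train_fresh(FAST_MODEL, tiny_training_setup, cfg)
        assert h1.loss == h2.loss
        assert h1.accuracy == h2.accuracy

    def test_history_length_and_empty_manifest(self, tiny_training_setup):
        cfg = TrainingConfig(epochs=2, batch_size=4, peak_lr=1e-3, seed=0,
                             preprocess=FAST_PREPROCESS)
        _, history = train_fresh(FAST_MODEL, tiny_training_setup, cfg)
        assert len(history) == 2
        from pneumofusion.fixtures import DatasetManifest
        from pneumofusion.training import train
        with pytest.raises(ValueError):
            train(PneumoniaAttentionNet(FAST_MODEL), DatasetManifest(), cfg)

    def test_checkpoint_roundtrip_bit_exact(self, tiny_training_setup,
                                            tmp_path):
        cfg = TrainingConfig(epochs=1, batch_size=8, peak_lr=1e-3, seed=2,
                             preprocess=FAST_PREPROCESS)
        model, _ = train_fresh(FAST_MODEL, tiny_training_setup, cfg)
        x = np.random.default_rng(3).random((2, 32, 32, 3), dtype=np.float32)
        before = model.predict_proba(x)
        path = tmp_path / "ckpt.npz"
        model.save_checkpoint(path)
        clone = PneumoniaAttentionNet(replace(FAST_MODEL, seed=cfg.seed))
        clone.load_checkpoint(path)
        after = clone.predict_proba(x)
        np.testing.assert_array_equal(before, after)
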