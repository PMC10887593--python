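"""Feature fusion, residual enhancement, attention augmentation, dynamic
attention pooling — hand-computed and brute-force reference checks."""

from __future__ import annotations

import numpy as np
import pytest

from pneumofusion.fusion import (AttentionAugmentation, ChannelAttention,
                                 DynamicAttentionPooling, FeatureFusion,
                                 FusionConfig, ResidualBlock, global_avg_pool)
from pneumofusion.nn import Tensor


def sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def _identity_bn(bn):
    bn.set_identity()


class TestChannelAttention:
    def test_zero_weights_give_half(self):
        att = ChannelAttention(3, np.random.default_rng(0))
        att.conv.weight.data[:] = 0
        out = att(Tensor(np.random.default_rng(1).random((1, 4, 4, 3),
                                                         dtype=np.float32)))
        np.testing.assert_allclose(out.numpy(), 0.5, atol=1e-7)

    def test_large_bias_saturates_to_one(self):
        att = ChannelAttention(2, np.random.default_rng(0))
        att.conv.weight.data[:] = 0
        att.conv.bias.data[:] = 50.0
        out = att(Tensor(np.zeros((1, 2, 2, 2), np.float32)))
        np.testing.assert_allclose(out.numpy(), 1.0, atol=1e-6)

    def test_diagonal_kernel_hand_sigmoid(self):
        att = ChannelAttention(2, np.random.default_rng(0))
        att.conv.weight.data = np.eye(2, dtype=np.float32).reshape(1, 1, 2, 2)
        att.conv.bias.data[:] = 0
        fmap = np.array([3.0, -3.0], np.float32).reshape(1, 1, 1, 2)
        out = att(Tensor(fmap)).numpy().reshape(-1)
        np.testing.assert_allclose(out, [0.9526, 0.0474], atol=5e-5)

    @pytest.mark.parametrize("seed", range(3))
    def test_gate_always_in_unit_interval(self, seed):
        rng = np.random.default_rng(seed)
        att = ChannelAttention(5, rng)
        att.conv.weight.data = 10 * rng.standard_normal(
            att.conv.weight.shape).astype(np.float32)
        out = att(Tensor(rng.standard_normal((2, 3, 3, 5)).astype(
            np.float32))).numpy()
        assert (out >= 0).all() and (out <= 1).all()


class TestFeatureFusion:
    def test_output_shape_contract(self):
        rng = np.random.default_rng(0)
        fusion = FeatureFusion(20, 12, FusionConfig(), rng)
        out = fusion(Tensor(rng.random((3, 5, 5, 20), dtype=np.float32)),
                     Tensor(rng.random((3, 4, 4, 12), dtype=np.float32)))
        assert out.shape == (3, 7, 7, 16)

    def test_zero_inputs_propagate_to_zero(self):
        rng = np.random.default_rng(1)
        fusion = FeatureFusion(4, 4, FusionConfig(), rng)
        out = fusion(Tensor(np.zeros((1, 2, 2, 4), np.float32)),
                     Tensor(np.zeros((1, 2, 2, 4), np.float32)))
        np.testing.assert_allclose(out.numpy(), 0.0, atol=1e-7)

    def test_hand_traced_scalar_example(self):
        """1x1x1 branches 2 and 4, attention 0.5, all-ones projections."""
        rng = np.random.default_rng(2)
        fusion = FeatureFusion(1, 1, FusionConfig(), rng)
        for att in (fusion.att_eff, fusion.att_dense):
            att.conv.weight.data[:] = 0
            att.conv.bias.data[:] = 0
        for proj in (fusion.proj_eff, fusion.proj_dense):
            proj.weight.data[:] = 1.0
            proj.bias.data[:] = 0.0
        out = fusion(Tensor(np.full((1, 1, 1, 1), 2.0, np.float32)),
                     Tensor(np.full((1, 1, 1, 1), 4.0, np.float32)))
        np.testing.assert_allclose(out.numpy(), 3.0, atol=1e-6)

    def test_matches_plain_numpy_reference(self):
        """Random weights: module output equals a step-by-step re-computation."""
        rng = np.random.default_rng(3)
        cfg = FusionConfig()
        fusion = FeatureFusion(6, 4, cfg, rng)
        fa = rng.standard_normal((2, 3, 3, 6)).astype(np.float32)
        fb = rng.standard_normal((2, 2, 2, 4)).astype(np.float32)
        out = fusion(Tensor(fa), Tensor(fb)).numpy()

        def branch(fmap, att, proj):
            gate = sigmoid(fmap @ att.conv.weight.data.reshape(
                fmap.shape[-1], fmap.shape[-1]) + att.conv.bias.data)
            pooled = (fmap * gate).mean(axis=(1, 2))
            return np.maximum(pooled @ proj.weight.data + proj.bias.data, 0)

        fused = branch(fa, fusion.att_eff, fusion.proj_eff) + \
            branch(fb, fusion.att_dense, fusion.proj_dense)
        np.testing.assert_allclose(out, fused.reshape(2, 7, 7, 16),
                                   atol=1e-5)

    def test_inconsistent_config_rejected(self):
        with pytest.raises(ValueError):
            FusionConfig(projection_units=100, reshape_target=(7, 7, 16))


class TestResidualBlock:
    def test_zero_weights_identity_on_nonnegative_input(self):
        rng = np.random.default_rng(0)
        block = ResidualBlock(16, 16, rng)
        for conv in (block.conv1, block.conv2):
            conv.weight.data[:] = 0
            conv.bias.data[:] = 0
        _identity_bn(block.bn1)
        _identity_bn(block.bn2)
        fmap = np.abs(rng.standard_normal((1, 5, 5, 16))).astype(np.float32)
        np.testing.assert_allclose(block(Tensor(fmap)).numpy(), fmap,
                                   atol=1e-5)

    def test_projection_shortcut_shape(self):
        block = ResidualBlock(16, 256, np.random.default_rng(1))
        out = block(Tensor(np.random.default_rng(2).standard_normal(
            (1, 7, 7, 16)).astype(np.float32)))
        assert out.shape == (1, 7, 7, 256)

    @pytest.mark.parametrize("seed", range(3))
    def test_output_nonnegative(self, seed):
        rng = np.random.default_rng(seed)
        block = ResidualBlock(4, 8, rng)
        out = block(Tensor(rng.standard_normal((2, 3, 3, 4)).astype(
            np.float32)))
        assert (out.numpy() >= 0).all()


class TestAttentionAugmentation:
    def test_hand_traced_identity_weights(self):
        """[1, -1] -> gate [sigmoid(1), sigmoid(0)] -> [0.7311, -0.5]."""
        rng = np.random.default_rng(0)
        aug = AttentionAugmentation(2, rng)
        for dense in (aug.dense1, aug.dense2):
            dense.weight.data = np.eye(2, dtype=np.float32)
            dense.bias.data[:] = 0
        _identity_bn(aug.bn1)
        _identity_bn(aug.bn2)
        fmap = np.array([1.0, -1.0], np.float32).reshape(1, 1, 1, 2)
        out = aug(Tensor(fmap)).numpy().reshape(-1)
        np.testing.assert_allclose(out, [0.7311, -0.5], atol=5e-5)

    @pytest.mark.parametrize("seed", range(3))
    def test_gate_contracts_with_identity_batchnorm(self, seed):
        rng = np.random.default_rng(seed)
        aug = AttentionAugmentation(6, rng)
        _identity_bn(aug.bn1)
        _identity_bn(aug.bn2)
        fmap = rng.standard_normal((2, 4, 4, 6)).astype(np.float32)
        out = aug(Tensor(fmap)).numpy()
        assert (np.abs(out) <= np.abs(fmap) + 1e-6).all()

    def test_zero_input_zero_output(self):
        aug = AttentionAugmentation(3, np.random.default_rng(1))
        out = aug(Tensor(np.zeros((1, 2, 2, 3), np.float32)))
        np.testing.assert_allclose(out.numpy(), 0.0, atol=1e-7)


class TestDynamicAttentionPooling:
    def test_saturated_gate_equals_plain_gap(self):
        rng = np.random.default_rng(0)
        pool = DynamicAttentionPooling(5, rng)
        pool.gate_conv.bias.data[:] = 60.0
        fmap = rng.standard_normal((2, 4, 4, 5)).astype(np.float32)
        out = pool(Tensor(fmap)).numpy()
        np.testing.assert_allclose(out, fmap.mean(axis=(1, 2)), atol=1e-5)

    def test_hand_computed_half_gate(self):
        pool = DynamicAttentionPooling(1, np.random.default_rng(0))
        pool.gate_conv.weight.data[:] = 0
        pool.gate_conv.bias.data[:] = 0
        fmap = np.array([[1.0, 2.0], [3.0, 4.0]],
                        np.float32).reshape(1, 2, 2, 1)
        out = pool(Tensor(fmap)).numpy()
        np.testing.assert_allclose(out, [[1.25]], atol=1e-6)

    def test_zero_input_zero_vector(self):
        pool = DynamicAttentionPooling(3, np.random.default_rng(2))
        out = pool(Tensor(np.zeros((1, 3, 3, 3), np.float32)))
        np.testing.assert_allclose(out.numpy(), 0.0, atol=1e-7)

    @pytest.mark.parametrize("seed", range(3))
    def test_gate_in_unit_interval(self, seed):
        rng = np.random.default_rng(seed)
        pool = DynamicAttentionPooling(4, rng)
        pool(Tensor(rng.standard_normal((1, 5, 5, 4)).astype(np.float32)))
        gate = pool.activations["pooling/gate"].numpy()
        assert (gate >= 0).all() and (gate <= 1).all()


def test_global_avg_pool_matches_numpy():
    rng = np.random.default_rng(0)
    fmap = rng.standard_normal((3, 5, 6, 7)).astype(np.float32)
    np.testing.assert_allclose(global_avg_pool(Tensor(fmap)).numpy(),
                               fmap.mean(axis=(1, 2)), atol=1e-6)
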