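"""CoAtNet / Enhanced CoAtNet blocks, forward contracts, and training."""

import numpy as np
import pytest

from leafensemble._autograd import Tensor
from leafensemble.classification import (CoAtNet, CoAtNetConfig, EnhancedCoAtNet,
                                         EnhancedCoAtNetConfig, GlobalAttention,
                                         apply_dropout, batch_normalize,
                                         build_classifier, coatnet_forward,
                                         conv_block, cross_entropy,
                                         enhanced_coatnet_forward, ffn_block,
                                         multiscale_aggregate,
                                         predict_probabilities, train_classifier)
from leafensemble.segmentation import TrainConfig
from leafensemble.synthetic import ValidationError


class TestConvBlock:
    def test_zero_kernel_relu_gives_zeros(self, rng):
        x = rng.normal(size=(1, 2, 4, 4)).astype(np.float32)
        out = conv_block(x, np.zeros((3, 2, 3, 3)), np.zeros(3))
        np.testing.assert_array_equal(out, 0.0)

    def test_identity_1x1_kernel_is_activation(self, rng):
        x = rng.normal(size=(1, 2, 4, 4)).astype(np.float32)
        w = np.eye(2).reshape(2, 2, 1, 1)
        out = conv_block(x, w, np.zeros(2), activation="relu")
        np.testing.assert_allclose(out, np.maximum(x, 0), atol=1e-6)

    def test_hand_computed_correlation(self):
        """3x3 kernel on a 4x4 input: interior values match the sliding
        dot product computed by hand."""
        x = np.arange(16, dtype=np.float32).reshape(1, 1, 4, 4)
        w = np.zeros((1, 1, 3, 3), np.float32)
        w[0, 0, 1, 1] = 2.0     # pure center tap: out = 2 * x
        w[0, 0, 0, 0] = 1.0     # plus top-left neighbor
        out = conv_block(x, w, np.zeros(1))
        # at (1,1): 2*x[1,1] + x[0,0] = 2*5 + 0 = 10
        assert out[0, 0, 1, 1] == 10.0
        # at (2,2): 2*10 + 5 = 25
        assert out[0, 0, 2, 2] == 25.0


class TestAttentionAndFFN:
    def test_attention_rows_sum_to_one(self, rng):
        ga = GlobalAttention(8, 2, np.random.default_rng(0))
        x = Tensor(rng.normal(size=(1, 5, 8)).astype(np.float32))
        b, T, c = x.shape
        hd = c // ga.n_heads
        q = ga.q(x).reshape(b, T, 2, hd).transpose(0, 2, 1, 3)
        k = ga.k(x).reshape(b, T, 2, hd).transpose(0, 2, 1, 3)
        attn = ((q @ k.transpose(0, 1, 3, 2)) * (1 / np.sqrt(hd))).softmax(-1)
        np.testing.assert_allclose(attn.data.sum(-1), 1.0, atol=1e-6)

    def test_identical_keys_give_uniform_weights(self, rng):
        """Two tokens with identical keys receive exactly (0.5, 0.5)."""
        ga = GlobalAttention(4, 1, np.random.default_rng(1))
        tok = np.tile(rng.normal(size=(1, 1, 4)).astype(np.float32), (1, 2, 1))
        out = ga.attend(Tensor(tok)).data
        v = tok[0] @ ga.v.weight.data + ga.v.bias.data
        want = (0.5 * v[0] + 0.5 * v[1]) @ ga.proj.weight.data + ga.proj.bias.data
        np.testing.assert_allclose(out[0, 0], want, atol=1e-5)

    def test_ffn_zero_weights_is_residual_passthrough(self, rng):
        x = rng.normal(size=(3, 4)).astype(np.float32)
        out = ffn_block(x, np.zeros((4, 8)), np.zeros(8), np.zeros((8, 4)),
                        np.zeros(4))
        np.testing.assert_allclose(out, x, atol=1e-6)

    def test_ffn_hand_example(self):
        x = np.array([[1.0, -1.0]], np.float32)
        w1 = np.array([[1.0, 0.0], [0.0, 1.0]], np.float32)
        w2 = np.array([[2.0, 0.0], [0.0, 2.0]], np.float32)
        out = ffn_block(x, w1, np.zeros(2), w2, np.zeros(2))
        # hidden = relu([1,-1]) = [1,0]; out = [2,0] + residual [1,-1]
        np.testing.assert_allclose(out, [[3.0, -1.0]], atol=1e-6)


class TestMultiscaleAggregate:
    def test_single_scale_is_identity(self, rng):
        f = rng.normal(size=(1, 2, 4, 4)).astype(np.float32)
        out = multiscale_aggregate([f], np.array([123.0]), (4, 4))
        np.testing.assert_allclose(out, f, atol=1e-6)

    def test_identical_maps_any_alpha(self, rng):
        f = rng.normal(size=(1, 2, 4, 4)).astype(np.float32)
        out = multiscale_aggregate([f, f, f], np.array([2.0, -1.0, 0.5]), (4, 4))
        np.testing.assert_allclose(out, f, atol=1e-5)

    def test_two_scalar_maps_weighted_mean(self):
        """alpha = softmax(logits) = (0.25, 0.75) on values 2 and 6 -> 5."""
        a = np.full((1, 1, 1, 1), 2.0, np.float32)
        b = np.full((1, 1, 1, 1), 6.0, np.float32)
        logits = np.log([0.25, 0.75])
        out = multiscale_aggregate([a, b], logits, (1, 1))
        np.testing.assert_allclose(out, 5.0, atol=1e-6)

    def test_convex_envelope_property(self, rng):
        """Aggregate lies in the elementwise min/max envelope of the inputs
        for any logits (convex combination)."""
        maps = [rng.normal(size=(1, 3, 4, 4)).astype(np.float32) for _ in range(3)]
        for _ in range(5):
            logits = rng.normal(size=3) * 3
            out = multiscale_aggregate(maps, logits, (4, 4))
            stack = np.stack(maps)
            assert (out >= stack.min(axis=0) - 1e-5).all()
            assert (out <= stack.max(axis=0) + 1e-5).all()

    def test_empty_list_raises(self):
        with pytest.raises(ValidationError):
            multiscale_aggregate([], np.array([]), (4, 4))


class TestNormalizationOps:
    def test_batch_norm_standardizes(self, rng):
        x = rng.normal(3.0, 2.0, size=(8, 4, 5, 5)).astype(np.float32)
        out = batch_normalize(x, np.ones(4), np.zeros(4))
        assert abs(out.mean(axis=(0, 2, 3))).max() < 1e-4
        np.testing.assert_allclose(out.var(axis=(0, 2, 3)), 1.0, atol=1e-2)

    def test_constant_channel_maps_to_shift(self):
        x = np.full((4, 1, 2, 2), 7.0, np.float32)
        out = batch_normalize(x, np.ones(1), np.full(1, 1.5))
        np.testing.assert_allclose(out, 1.5, atol=1e-2)

    def test_two_value_hand_case(self):
        """Batch {1, 3}: mu=2, sigma=1, gamma=2, beta=1 -> {-1, 3}."""
        x = np.array([1.0, 3.0], np.float32).reshape(2, 1, 1, 1)
        out = batch_normalize(x, np.full(1, 2.0), np.ones(1), eps=1e-12)
        np.testing.assert_allclose(out.ravel(), [-1.0, 3.0], atol=1e-3)

    def test_batch_of_one_raises_in_training(self):
        with pytest.raises(ValueError):
            batch_normalize(np.ones((1, 2, 3, 3), np.float32),
                            np.ones(2), np.zeros(2), mode="train")

    def test_dropout_expectation_preserved(self):
        x = np.ones((1000, 100), np.float32)
        out = apply_dropout(x, 0.5, mode="train", seed=0)
        assert abs(out.mean() - 1.0) < 0.02
        np.testing.assert_array_equal(apply_dropout(x, 0.7, mode="eval"), x)
        with pytest.raises(ValueError):
            apply_dropout(x, 1.0)


class TestForwardContracts:
    def test_simplex_output(self, rng, tiny_coatnet_config, tiny_enhanced_config):
        img = rng.random((2, 64, 64, 3)).astype(np.float32)
        for arch, kw in (("coatnet", {"coatnet_config": tiny_coatnet_config}),
                         ("enhanced", {"enhanced_config": tiny_enhanced_config})):
            model = build_classifier(arch, 0, **kw)
            p = coatnet_forward(img, model)
            assert p.shape == (2, 3)
            assert (p >= 0).all()
            np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-6)

    def test_zero_head_gives_uniform(self, rng, tiny_coatnet_config):
        model = build_classifier("coatnet", 0, coatnet_config=tiny_coatnet_config)
        model.head.weight.data[:] = 0
        model.head.bias.data[:] = 0
        p = coatnet_forward(rng.random((64, 64, 3)).astype(np.float32), model)
        np.testing.assert_allclose(p, 1 / 3, atol=1e-6)

    def test_permuting_head_rows_permutes_probabilities(self, rng,
                                                        tiny_coatnet_config):
        model = build_classifier("coatnet", 0, coatnet_config=tiny_coatnet_config)
        img = rng.random((64, 64, 3)).astype(np.float32)
        p = coatnet_forward(img, model)
        perm = [2, 0, 1]
        model.head.weight.data = model.head.weight.data[:, perm]
        model.head.bias.data = model.head.bias.data[perm]
        p2 = coatnet_forward(img, model)
        np.testing.assert_allclose(p2, p[..., perm], atol=1e-5)

    def test_alpha_logit_shift_invariance(self, rng, tiny_enhanced_config):
        model = build_classifier("enhanced", 0, enhanced_config=tiny_enhanced_config)
        model.eval()
        img = rng.random((64, 64, 3)).astype(np.float32)
        p = enhanced_coatnet_forward(img, model)
        model.alpha_logits.data = model.alpha_logits.data + 7.0
        p2 = enhanced_coatnet_forward(img, model)
        np.testing.assert_allclose(p, p2, atol=1e-5)

    def test_lambda_zero_kills_attention_branch(self, rng, tiny_enhanced_config):
        model = build_classifier("enhanced", 1, enhanced_config=tiny_enhanced_config)
        model.eval()
        img = rng.random((64, 64, 3)).astype(np.float32)
        model.lambda2.data = np.asarray(0.0, np.float32)
        p_before = enhanced_coatnet_forward(img, model)
        # with lambda2 = 0 the attention branch weights are irrelevant
        for mod in (model.attn_branch,):
            for param in mod.parameters():
                param.data = param.data + 1.0
        p_after = enhanced_coatnet_forward(img, model)
        np.testing.assert_allclose(p_before, p_after, atol=1e-5)

    def test_n_scales_exceeding_stages_raises(self, tiny_coatnet_config):
        with pytest.raises(ValidationError):
            EnhancedCoAtNetConfig(base=tiny_coatnet_config, n_scales=5)

    def test_transformer_first_layout_rejected(self):
        with pytest.raises(ValidationError):
            CoAtNetConfig(stage_layout=("transformer", "conv"),
                          channels=(8, 8), blocks_per_stage=(1, 1),
                          n_classes=3, input_size=64)


class TestTraining:
    def test_smoke_one_epoch(self, tiny_dataset, tiny_coatnet_config):
        cfg = TrainConfig(epochs=1, batch_size=8, seed=0)
        _, hist = train_classifier(tiny_dataset[::6], "coatnet", cfg,
                                   coatnet_config=tiny_coatnet_config)
        assert len(hist["train_loss"]) == 1
        assert np.isfinite(hist["train_loss"][0])

    def test_seed_reproducibility(self, tiny_dataset, tiny_coatnet_config):
        cfg = TrainConfig(epochs=2, batch_size=8, seed=5)
        _, h1 = train_classifier(tiny_dataset[::4], "coatnet", cfg,
                                 coatnet_config=tiny_coatnet_config)
        _, h2 = train_classifier(tiny_dataset[::4], "coatnet", cfg,
                                 coatnet_config=tiny_coatnet_config)
        assert h1["train_loss"] == h2["train_loss"]
        assert h1["val_acc"] == h2["val_acc"]

    def test_single_class_dataset_raises(self, tiny_dataset, tiny_coatnet_config):
        only_zero = [s for s in tiny_dataset if s.label == 0]
        with pytest.raises(ValidationError):
            train_classifier(only_zero, "coatnet", TrainConfig(epochs=1),
                             coatnet_config=tiny_coatnet_config)

    def test_cross_entropy_value(self):
        probs = Tensor(np.array([[0.8, 0.2], [0.4, 0.6]], np.float32))
        loss = cross_entropy(probs, np.array([0, 1]))
        want = -(np.log(0.8) + np.log(0.6)) / 2
        assert float(loss.data) == pytest.approx(want, rel=1e-5)
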