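"""Segmentation: U-Net contracts, windowed attention vs dense oracle,
shift masking, patch ops, ensemble rules, ROI extraction, training."""

import numpy as np
import pytest

from leafensemble._autograd import Tensor
from leafensemble.segmentation import (PatchEmbed, PatchMerge, SegEnsembleConfig,
                                       SwinBlock, SwinSegConfig, SwinSegmenter,
                                       TrainConfig, UNet, UNetConfig,
                                       WindowAttention, dice_coefficient,
                                       ensemble_segment, extract_roi, patch_embed,
                                       patch_merge, shift_attention_mask,
                                       train_segmenter, unet_forward,
                                       window_attention)
from leafensemble.synthetic import ValidationError


class TestUNet:
    def test_resolution_restored_and_range(self, rng):
        model = UNet(UNetConfig(depth=4, base_channels=4), rng)
        img = rng.random((64, 64, 3)).astype(np.float32)
        out = unet_forward(img, model)
        assert out.shape == (64, 64)
        assert (out > 0).all() and (out < 1).all()

    def test_zero_weights_give_half_probability(self, rng):
        model = UNet(UNetConfig(depth=2, base_channels=4), rng)
        for p in model.parameters():
            p.data[:] = 0
        out = unet_forward(np.zeros((32, 32, 3), np.float32), model)
        np.testing.assert_allclose(out, 0.5)

    def test_bottleneck_shape_follows_doubling_rule(self, rng):
        """64 px at depth 4, base 16: bottleneck side 64/2^4 = 4 and
        channels 16 * 2^4 = 256."""
        model = UNet(UNetConfig(depth=4, base_channels=16), rng)
        x = Tensor(rng.random((1, 3, 64, 64)).astype(np.float32))
        for conv in model.enc:
            x = conv(x).relu().maxpool2d(2)
        bott = model.bottleneck(x).relu()
        assert bott.shape == (1, 256, 4, 4)

    def test_indivisible_side_raises(self, rng):
        model = UNet(UNetConfig(depth=4, base_channels=4), rng)
        with pytest.raises(ValidationError, match="divisible"):
            unet_forward(np.zeros((40, 40, 3), np.float32), model)


class TestWindowAttention:
    def test_full_window_equals_dense_attention(self, rng):
        """Window covering the whole grid with no shift reproduces a
        brute-force dense attention computed with plain numpy."""
        for side in (4, 8):
            wa = WindowAttention(16, 2, side, 0, np.random.default_rng(side))
            tok = rng.normal(size=(1, side, side, 16)).astype(np.float32)
            got = wa(Tensor(tok)).data[0]

            t = tok[0].reshape(side * side, 16)
            q = t @ wa.q.weight.data + wa.q.bias.data
            k = t @ wa.k.weight.data + wa.k.bias.data
            v = t @ wa.v.weight.data + wa.v.bias.data
            out = np.zeros_like(t)
            hd = 8
            for h in range(2):
                sl = slice(h * hd, (h + 1) * hd)
                a = q[:, sl] @ k[:, sl].T / np.sqrt(hd)
                a = np.exp(a - a.max(1, keepdims=True))
                a /= a.sum(1, keepdims=True)
                out[:, sl] = a @ v[:, sl]
            want = (out @ wa.proj.weight.data + wa.proj.bias.data).reshape(side, side, 16)
            np.testing.assert_allclose(got, want, atol=1e-5)

    def test_shift_mask_blocks_wrapped_pairs(self, rng):
        """On a 4x4 grid with window 2 and shift 1, attention mass between
        tokens whose pre-shift windows differ across the wrap boundary is
        exactly zero (checked against the enumerated mask oracle)."""
        wa = WindowAttention(8, 2, 2, 1, np.random.default_rng(3))
        tok = rng.normal(size=(1, 4, 4, 8)).astype(np.float32)
        weights = wa.attention_weights(Tensor(tok))      # (nW, heads, T, T)
        mask = shift_attention_mask(4, 2, 1)
        forbidden = np.broadcast_to(mask[:, None], weights.shape) < 0
        assert weights[forbidden].max() == 0.0
        np.testing.assert_allclose(weights.sum(-1), 1.0, atol=1e-6)

    def test_mask_oracle_region_enumeration(self):
        """Independent enumeration: roll the region-id grid and compare
        pairwise-equality mask windows."""
        side, w, s = 4, 2, 1
        ids = np.zeros((side, side), int)
        # three-slice partition of the shifted canvas
        sl = (slice(0, -w), slice(-w, -s), slice(-s, None))
        c = 0
        for hs in sl:
            for ws in sl:
                ids[hs, ws] = c
                c += 1
        wins = ids.reshape(side // w, w, side // w, w).transpose(0, 2, 1, 3)
        wins = wins.reshape(-1, w * w)
        want = np.where(wins[:, :, None] != wins[:, None, :], -1e9, 0.0)
        np.testing.assert_array_equal(shift_attention_mask(side, w, s), want)

    def test_single_token_window_returns_value_projection(self, rng):
        wa = WindowAttention(8, 2, 1, 0, np.random.default_rng(0))
        tok = rng.normal(size=(1, 2, 2, 8)).astype(np.float32)
        got = wa(Tensor(tok)).data
        flat = tok.reshape(4, 8)
        v = flat @ wa.v.weight.data + wa.v.bias.data
        want = (v @ wa.proj.weight.data + wa.proj.bias.data).reshape(1, 2, 2, 8)
        np.testing.assert_allclose(got, want, atol=1e-5)

    def test_shift_must_be_smaller_than_window(self):
        with pytest.raises(ValidationError):
            WindowAttention(8, 2, 2, 2, np.random.default_rng(0))


class TestPatchOps:
    def test_embed_shape_and_constant_symmetry(self, rng):
        pe = PatchEmbed(32, 4, 32, np.random.default_rng(0))
        img = rng.random((32, 32, 3)).astype(np.float32)
        grid = patch_embed(img, pe)
        assert grid.shape == (8, 8, 32)
        const = np.full((32, 32, 3), 0.5, np.float32)
        grid_c = patch_embed(const, pe) - pe.pos.data[0]
        assert np.abs(grid_c - grid_c[0, 0]).max() < 1e-5

    def test_embed_matches_hand_projection(self, rng):
        pe = PatchEmbed(4, 4, 8, np.random.default_rng(1))
        img = rng.random((4, 4, 3)).astype(np.float32)
        got = patch_embed(img, pe)[0, 0]
        flat = img.transpose(2, 0, 1).reshape(-1)       # channel-major patch
        want = flat @ pe.proj.weight.data + pe.proj.bias.data + pe.pos.data[0, 0, 0]
        np.testing.assert_allclose(got, want, atol=1e-5)

    def test_merge_shapes_and_hand_value(self, rng):
        pm = PatchMerge(32, np.random.default_rng(0))
        grid = rng.normal(size=(8, 8, 32)).astype(np.float32)
        merged = patch_merge(grid, pm)
        assert merged.shape == (4, 4, 64)
        pm2 = PatchMerge(2, np.random.default_rng(1))
        g2 = rng.normal(size=(2, 2, 2)).astype(np.float32)
        got = patch_merge(g2, pm2)[0, 0]
        concat = np.concatenate([g2[0, 0], g2[0, 1], g2[1, 0], g2[1, 1]])
        want = concat @ pm2.proj.weight.data + pm2.proj.bias.data
        np.testing.assert_allclose(got, want, atol=1e-5)

    def test_merge_rejects_odd_grid(self, rng):
        pm = PatchMerge(4, np.random.default_rng(0))
        with pytest.raises(ValidationError):
            patch_merge(rng.normal(size=(3, 3, 4)).astype(np.float32), pm)


class TestSwinBlock:
    def test_zero_branches_reduce_to_layer_norm(self, rng):
        blk = SwinBlock(8, 2, 2, 0, 2, np.random.default_rng(0))
        for name, p in blk.named_parameters():
            if "gamma" not in name:
                p.data[:] = 0
        x = rng.normal(size=(1, 4, 4, 8)).astype(np.float32)
        out = blk(Tensor(x)).data
        mu = x.mean(-1, keepdims=True)
        sd = x.std(-1, keepdims=True)
        np.testing.assert_allclose(out, (x - mu) / np.sqrt(sd ** 2 + 1e-5), atol=1e-4)

    def test_layer_norm_statistics(self, rng):
        x = Tensor(rng.normal(2.0, 3.0, size=(5, 7, 16)).astype(np.float32))
        from leafensemble.nn import LayerNorm
        out = LayerNorm(16)(x).data
        np.testing.assert_allclose(out.mean(-1), 0.0, atol=1e-5)
        np.testing.assert_allclose(out.var(-1), 1.0, atol=1e-3)


class TestSwinSegmenter:
    def test_resolution_and_range(self, rng):
        cfg = SwinSegConfig(input_size=32, embed_dim=16, depths=(2, 2),
                            n_heads=(2, 2), window_size=4)
        model = SwinSegmenter(cfg, np.random.default_rng(0))
        img = rng.random((32, 32, 3)).astype(np.float32)
        from leafensemble.segmentation import swin_segment_forward
        out = swin_segment_forward(img, model)
        assert out.shape == (32, 32)
        assert (out > 0).all() and (out < 1).all()

    def test_stage_grids_follow_merge_arithmetic(self, rng):
        cfg = SwinSegConfig(input_size=32, embed_dim=16, depths=(2, 2),
                            n_heads=(2, 2), window_size=4)
        model = SwinSegmenter(cfg, np.random.default_rng(0))
        x = Tensor(rng.random((1, 3, 32, 32)).astype(np.float32))
        t = model.embed(x)
        assert t.shape == (1, 8, 8, 16)
        for blk in model.stages[0]:
            t = blk(t)
        t = model.merges[0](t)
        assert t.shape == (1, 4, 4, 32)

    def test_invalid_window_grid_combo(self):
        with pytest.raises(ValidationError):
            SwinSegConfig(input_size=32, window_size=3)


class TestEnsembleAndROI:
    def test_identical_maps_any_rule(self, rng):
        m = rng.random((16, 16))
        for rule in ("mean_probability", "max_probability"):
            out = ensemble_segment([m, m], SegEnsembleConfig(combine_rule=rule))
            np.testing.assert_array_equal(out, (m >= 0.5).astype(np.uint8))

    def test_mean_rule_arithmetic_and_tie(self):
        a = np.full((2, 2), 0.4)
        b = np.full((2, 2), 0.8)
        out = ensemble_segment([a, b], SegEnsembleConfig())
        np.testing.assert_array_equal(out, 1)     # 0.6 >= 0.5
        tie = ensemble_segment([np.full((2, 2), 0.5)], SegEnsembleConfig())
        np.testing.assert_array_equal(tie, 1)     # score == threshold is foreground

    def test_weighted_rule_degenerate_weights(self, rng):
        a, b = rng.random((8, 8)), rng.random((8, 8))
        cfg = SegEnsembleConfig(combine_rule="weighted", member_weights=(1.0, 0.0))
        np.testing.assert_array_equal(ensemble_segment([a, b], cfg),
                                      (a >= 0.5).astype(np.uint8))

    def test_shape_mismatch_raises(self, rng):
        with pytest.raises(ValidationError):
            ensemble_segment([rng.random((4, 4)), rng.random((5, 5))],
                             SegEnsembleConfig())

    def test_roi_bounding_box(self, rng):
        img = rng.random((32, 32, 3)).astype(np.float32)
        mask = np.zeros((32, 32), np.uint8)
        mask[8:18, 4:14] = 1
        out = extract_roi(img, mask, pad_fraction=0.0)
        assert out.shape == (10, 10, 3)
        np.testing.assert_allclose(out, img[8:18, 4:14])

    def test_roi_empty_mask_passthrough(self, rng):
        img = rng.random((16, 16, 3)).astype(np.float32)
        out = extract_roi(img, np.zeros((16, 16), np.uint8), 0.1)
        np.testing.assert_array_equal(out, img)

    def test_roi_full_mask_noop_zeroing(self, rng):
        img = rng.random((16, 16, 3)).astype(np.float32)
        out = extract_roi(img, np.ones((16, 16), np.uint8), 0.0)
        np.testing.assert_allclose(out, img)


class TestTraining:
    def test_smoke_single_epoch(self, tiny_dataset):
        cfg = TrainConfig(epochs=1, batch_size=4, seed=0)
        model, hist = train_segmenter(tiny_dataset[:8], "unet", cfg,
                                      unet_config=UNetConfig(depth=2, base_channels=4))
        assert len(hist["train_loss"]) == 1
        assert np.isfinite(hist["train_loss"][0])
        assert np.isfinite(hist["val_loss"][0])

    def test_same_seed_reproducible(self, tiny_dataset):
        cfg = TrainConfig(epochs=2, batch_size=4, seed=3)
        kw = dict(unet_config=UNetConfig(depth=2, base_channels=4))
        _, h1 = train_segmenter(tiny_dataset[:12], "unet", cfg, **kw)
        _, h2 = train_segmenter(tiny_dataset[:12], "unet", cfg, **kw)
        assert h1["train_loss"] == h2["train_loss"]

    def test_empty_dataset_raises(self):
        with pytest.raises(ValidationError):
            train_segmenter([], "unet", TrainConfig(epochs=1))

    def test_dice_coefficient_definition(self):
        a = np.zeros((4, 4), bool)
        b = np.zeros((4, 4), bool)
        assert dice_coefficient(a, b) == 1.0
        a[0, 0] = True
        assert dice_coefficient(a, b) == 0.0
        b[0, 0] = True
        assert dice_coefficient(a, b) == pytest.approx(1.0, abs=1e-5)
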