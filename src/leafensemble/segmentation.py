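"""Lesion segmentation: U-Net, a shifted-window transformer segmenter,
their probability-map ensemble, ROI extraction, and a desk-scale trainer.

Both segmenters map an H x W x 3 image to an H x W map of foreground
(lesion) probabilities.  The U-Net is the classic encoder-decoder with
skip concatenations; the transformer segmenter embeds 4 x 4 patches,
runs window-based multi-head self-attention blocks — alternating plain
(W-MSA) and cyclically shifted (SW-MSA) windows with the standard
boundary mask — with patch merging between stages, and restores full
resolution with a light bilinear-upsampling head.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._autograd import Tensor, concatenate
from .nn import (Conv2d, ConvTranspose2d, LayerNorm, Linear, Module,
                 Parameter, make_optimizer)
from .synthetic import SyntheticSample, ValidationError

# --------------------------------------------------------------------------
# configs


@dataclass
class UNetConfig:
    depth: int = 4
    base_channels: int = 16
    conv_kernel: int = 3

    def __post_init__(self):
        if self.depth < 1:
            raise ValidationError("depth must be >= 1")
        if self.conv_kernel % 2 != 1:
            raise ValidationError("conv_kernel must be odd")


@dataclass
class SwinSegConfig:
    input_size: int = 64
    patch_size: int = 4
    embed_dim: int = 32
    depths: tuple[int, ...] = (2, 2)
    n_heads: tuple[int, ...] = (2, 4)
    window_size: int = 4
    shift_size: int | None = None      # default window_size // 2
    mlp_ratio: int = 4
    head_channels: int = 8

    def __post_init__(self):
        if self.shift_size is None:
            self.shift_size = self.window_size // 2
        if self.shift_size >= self.window_size:
            raise ValidationError("shift_size must be < window_size")
        if self.input_size % self.patch_size:
            raise ValidationError("input_size must be divisible by patch_size")
        side = self.input_size // self.patch_size
        for i in range(len(self.depths)):
            if side % self.window_size:
                raise ValidationError(
                    f"token grid side {side} at stage {i} not divisible by "
                    f"window_size {self.window_size}")
            side //= 2
        if len(self.n_heads) != len(self.depths):
            raise ValidationError("n_heads must have one entry per stage")


@dataclass
class TrainConfig:
    learning_rate: float = 0.001
    batch_size: int = 32
    optimizer: str = "adam"
    epochs: int = 200
    loss: str = "bce_dice"
    val_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValidationError("learning_rate must be > 0")
        if self.batch_size < 1:
            raise ValidationError("batch_size must be >= 1")
        if self.epochs < 1:
            raise ValidationError("epochs must be >= 1")


@dataclass
class SegEnsembleConfig:
    combine_rule: str = "mean_probability"
    member_weights: tuple[float, ...] | None = None
    threshold: float = 0.5

    def __post_init__(self):
        if self.combine_rule not in ("mean_probability", "max_probability", "weighted"):
            raise ValidationError(f"unknown combine_rule '{self.combine_rule}'")
        if not 0.0 < self.threshold < 1.0:
            raise ValidationError("threshold must be in (0, 1)")
        if self.combine_rule == "weighted":
            if self.member_weights is None:
                raise ValidationError("weighted rule needs member_weights")
            w = np.asarray(self.member_weights, dtype=float)
            if (w < 0).any() or abs(w.sum() - 1.0) > 1e-6:
                raise ValidationError("member_weights must be a simplex vector")


# --------------------------------------------------------------------------
# U-Net


class UNet(Module):
    """Encoder-decoder with skip concatenations.

    Encoder levels: conv + ReLU then 2x2 max pooling (spatial halving,
    channel doubling); decoder levels: transposed convolution (spatial
    doubling) then conv + ReLU on the concatenation with the matching
    encoder features; 1x1 conv + sigmoid head.
    """

    def __init__(self, config: UNetConfig, rng: np.random.Generator):
        super().__init__()
        self.config = config
        k = config.conv_kernel
        c = config.base_channels
        self.enc = []
        c_in = 3
        for lvl in range(config.depth):
            c_out = c * (2 ** lvl)
            self.enc.append(Conv2d(c_in, c_out, k, rng))
            c_in = c_out
        self.bottleneck = Conv2d(c_in, c_in * 2, k, rng)
        self.dec_up = []
        self.dec_conv = []
        c_bot = c_in * 2
        for lvl in reversed(range(config.depth)):
            c_skip = c * (2 ** lvl)
            self.dec_up.append(ConvTranspose2d(c_bot, c_skip, 2, rng, stride=2))
            self.dec_conv.append(Conv2d(c_skip * 2, c_skip, k, rng))
            c_bot = c_skip
        self.head = Conv2d(c_bot, 1, 1, rng, padding=0)

    def forward(self, x: Tensor) -> Tensor:
        """x: (N, 3, H, W) -> foreground probabilities (N, H, W)."""
        side = x.shape[-1]
        if side % (2 ** self.config.depth):
            raise ValidationError(
                f"input side {side} not divisible by 2^depth = {2 ** self.config.depth}")
        skips = []
        for conv in self.enc:
            x = conv(x).relu()
            skips.append(x)
            x = x.maxpool2d(2)
        x = self.bottleneck(x).relu()
        for up, conv, skip in zip(self.dec_up, self.dec_conv, reversed(skips)):
            x = up(x)
            x = concatenate([skip, x], axis=1)
            x = conv(x).relu()
        logits = self.head(x)
        n, _, h, w = logits.shape
        return logits.reshape(n, h, w).sigmoid()

    __call__ = forward


def unet_forward(image: np.ndarray, model: UNet) -> np.ndarray:
    """Probability map for one H x W x 3 image (or a batch N x H x W x 3)."""
    return _forward_numpy(image, model)


def _forward_numpy(image: np.ndarray, model) -> np.ndarray:
    arr = np.asarray(image, dtype=np.float32)
    single = arr.ndim == 3
    if single:
        arr = arr[None]
    x = Tensor(arr.transpose(0, 3, 1, 2))
    out = model.forward(x).data
    return out[0] if single else out


# --------------------------------------------------------------------------
# windowed attention


def _partition(x: Tensor, w: int) -> Tensor:
    """(B, H, W, C) -> (B * nWindows, w*w, C)."""
    b, h, wd, c = x.shape
    x = x.reshape(b, h // w, w, wd // w, w, c)
    x = x.transpose(0, 1, 3, 2, 4, 5)
    return x.reshape(b * (h // w) * (wd // w), w * w, c)


def _unpartition(x: Tensor, w: int, b: int, h: int, wd: int) -> Tensor:
    c = x.shape[-1]
    x = x.reshape(b, h // w, wd // w, w, w, c)
    x = x.transpose(0, 1, 3, 2, 4, 5)
    return x.reshape(b, h, wd, c)


def shift_attention_mask(side: int, window: int, shift: int) -> np.ndarray:
    """Additive attention mask for shifted windows on a ``side x side`` grid.

    Labels the cyclically shifted canvas with region ids using the
    three-slice partition; token pairs in the same window but different
    regions (i.e. wrapped across a boundary) get -1e9.
    Returns (n_windows, w*w, w*w).
    """
    img = np.zeros((side, side))
    slices = (slice(0, -window), slice(-window, -shift), slice(-shift, None))
    cnt = 0
    for hs in slices:
        for ws in slices:
            img[hs, ws] = cnt
            cnt += 1
    t = Tensor(img[None, :, :, None])
    wins = _partition(t, window).data[..., 0]           # (nW, w*w)
    diff = wins[:, :, None] != wins[:, None, :]
    return np.where(diff, -1e9, 0.0).astype(np.float32)


class WindowAttention(Module):
    """Multi-head scaled dot-product attention within square windows,
    optionally on a cyclically shifted grid with boundary masking."""

    def __init__(self, dim: int, n_heads: int, window_size: int, shift: int,
                 rng: np.random.Generator):
        super().__init__()
        if dim % n_heads:
            raise ValidationError(f"dim {dim} not divisible by n_heads {n_heads}")
        if shift >= window_size:
            raise ValidationError("shift must be < window_size")
        self.n_heads = n_heads
        self.window_size = window_size
        self.shift = shift
        self.q = Linear(dim, dim, rng)
        self.k = Linear(dim, dim, rng)
        self.v = Linear(dim, dim, rng)
        self.proj = Linear(dim, dim, rng)
        self._mask_cache: dict[int, np.ndarray] = {}

    def __call__(self, x: Tensor) -> Tensor:
        """x: (B, H, W, C) token grid -> same shape."""
        b, h, wd, c = x.shape
        w = self.window_size
        if h % w or wd % w:
            raise ValidationError(f"grid ({h},{wd}) not divisible by window {w}")
        if self.shift:
            x = x.roll((-self.shift, -self.shift), (1, 2))
        t = _partition(x, w)                                # (B*nW, T, C)
        bn, T, _ = t.shape
        hd = c // self.n_heads

        def heads(z: Tensor) -> Tensor:
            return z.reshape(bn, T, self.n_heads, hd).transpose(0, 2, 1, 3)

        q, k, v = heads(self.q(t)), heads(self.k(t)), heads(self.v(t))
        attn = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(hd))
        if self.shift:
            if h not in self._mask_cache:
                self._mask_cache[h] = shift_attention_mask(h, w, self.shift)
            mask = self._mask_cache[h]                      # (nW, T, T)
            n_win = mask.shape[0]
            tiled = np.broadcast_to(mask[None, :, None],
                                    (b, n_win, self.n_heads, T, T))
            attn = attn + Tensor(tiled.reshape(bn, self.n_heads, T, T))
        attn = attn.softmax(axis=-1)
        out = attn @ v                                      # (bn, heads, T, hd)
        out = out.transpose(0, 2, 1, 3).reshape(bn, T, c)
        out = self.proj(out)
        out = _unpartition(out, w, b, h, wd)
        if self.shift:
            out = out.roll((self.shift, self.shift), (1, 2))
        return out

    def attention_weights(self, x: Tensor) -> np.ndarray:
        """Post-softmax attention weights, (B*nW, heads, T, T); diagnostic."""
        b, h, wd, c = x.shape
        w = self.window_size
        if self.shift:
            x = x.roll((-self.shift, -self.shift), (1, 2))
        t = _partition(x, w)
        bn, T, _ = t.shape
        hd = c // self.n_heads

        def heads_(z):
            return z.reshape(bn, T, self.n_heads, hd).transpose(0, 2, 1, 3)

        q, k = heads_(self.q(t)), heads_(self.k(t))
        attn = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(hd))
        if self.shift:
            mask = shift_attention_mask(h, w, self.shift)
            tiled = np.broadcast_to(mask[None, :, None],
                                    (b, mask.shape[0], self.n_heads, T, T))
            attn = attn + Tensor(tiled.reshape(bn, self.n_heads, T, T))
        return attn.softmax(axis=-1).data


def window_attention(tokens: np.ndarray, params: WindowAttention) -> np.ndarray:
    """Functional wrapper: (H, W, C) or (B, H, W, C) array in and out."""
    arr = np.asarray(tokens, dtype=np.float32)
    single = arr.ndim == 3
    if single:
        arr = arr[None]
    out = params(Tensor(arr)).data
    return out[0] if single else out


class SwinBlock(Module):
    """Attention then MLP, each with residual and post-layer-norm
    (y = LN(x + Attn(x)); z = LN(y + MLP(y)))."""

    def __init__(self, dim: int, n_heads: int, window_size: int, shift: int,
                 mlp_ratio: int, rng: np.random.Generator):
        super().__init__()
        self.attn = WindowAttention(dim, n_heads, window_size, shift, rng)
        self.norm1 = LayerNorm(dim)
        self.norm2 = LayerNorm(dim)
        self.fc1 = Linear(dim, dim * mlp_ratio, rng)
        self.fc2 = Linear(dim * mlp_ratio, dim, rng)

    def __call__(self, x: Tensor) -> Tensor:
        y = self.norm1(x + self.attn(x))
        z = self.fc2(self.fc1(y).relu())
        return self.norm2(y + z)


class PatchEmbed(Module):
    """Flatten-then-linear patch projection plus learned absolute
    position embeddings."""

    def __init__(self, image_size: int, patch_size: int, dim: int,
                 rng: np.random.Generator):
        super().__init__()
        if image_size % patch_size:
            raise ValidationError("image side must be divisible by patch_size")
        self.patch = patch_size
        self.grid = image_size // patch_size
        self.proj = Linear(patch_size * patch_size * 3, dim, rng)
        self.pos = Parameter(
            rng.normal(0, 0.02, (1, self.grid, self.grid, dim)).astype(np.float32))

    def __call__(self, x: Tensor) -> Tensor:
        """x: (B, 3, H, W) -> (B, H/p, W/p, D)."""
        b, c, h, w = x.shape
        p = self.patch
        if h % p or w % p:
            raise ValidationError(f"image side ({h},{w}) not divisible by patch {p}")
        x = x.reshape(b, c, h // p, p, w // p, p)
        x = x.transpose(0, 2, 4, 1, 3, 5).reshape(b, h // p, w // p, c * p * p)
        return self.proj(x) + self.pos


def patch_embed(image: np.ndarray, params: PatchEmbed) -> np.ndarray:
    """Functional wrapper: (H, W, 3) image -> (H/p, W/p, D) token grid."""
    arr = np.asarray(image, dtype=np.float32)
    single = arr.ndim == 3
    if single:
        arr = arr[None]
    out = params(Tensor(arr.transpose(0, 3, 1, 2))).data
    return out[0] if single else out


class PatchMerge(Module):
    """Concatenate 2x2 token neighborhoods (4C) and project to 2C."""

    def __init__(self, dim: int, rng: np.random.Generator):
        super().__init__()
        self.proj = Linear(4 * dim, 2 * dim, rng)

    def __call__(self, x: Tensor) -> Tensor:
        b, h, w, c = x.shape
        if h % 2 or w % 2:
            raise ValidationError(f"patch merge needs even grid sides, got ({h},{w})")
        x = x.reshape(b, h // 2, 2, w // 2, 2, c)
        x = x.transpose(0, 1, 3, 2, 4, 5).reshape(b, h // 2, w // 2, 4 * c)
        return self.proj(x)


def patch_merge(tokens: np.ndarray, params: PatchMerge) -> np.ndarray:
    arr = np.asarray(tokens, dtype=np.float32)
    single = arr.ndim == 3
    if single:
        arr = arr[None]
    out = params(Tensor(arr)).data
    return out[0] if single else out


class SwinSegmenter(Module):
    """Hierarchical windowed-attention segmenter with a bilinear
    upsampling head (per-stage 1x1 conv -> upsample -> sum -> 1x1 conv)."""

    def __init__(self, config: SwinSegConfig, rng: np.random.Generator):
        super().__init__()
        self.config = config
        self.embed = PatchEmbed(config.input_size, config.patch_size,
                                config.embed_dim, rng)
        self.stages = []
        self.merges = []
        self.stage_heads = []
        dim = config.embed_dim
        for si, (depth, heads) in enumerate(zip(config.depths, config.n_heads)):
            blocks = []
            for bi in range(depth):
                shift = 0 if bi % 2 == 0 else config.shift_size
                blocks.append(SwinBlock(dim, heads, config.window_size, shift,
                                        config.mlp_ratio, rng))
            self.stages.append(blocks)
            self.stage_heads.append(Conv2d(dim, config.head_channels, 1, rng, padding=0))
            if si < len(config.depths) - 1:
                self.merges.append(PatchMerge(dim, rng))
                dim *= 2
        self.out_conv = Conv2d(config.head_channels, 1, 1, rng, padding=0)

    def forward(self, x: Tensor) -> Tensor:
        """x: (N, 3, H, W) -> probabilities (N, H, W)."""
        n, _, h, w = x.shape
        t = self.embed(x)
        acc = None
        for si, blocks in enumerate(self.stages):
            for blk in blocks:
                t = blk(t)
            fm = t.transpose(0, 3, 1, 2)
            head = self.stage_heads[si](fm).upsample_bilinear(h, w)
            acc = head if acc is None else acc + head
            if si < len(self.merges):
                t = self.merges[si](t)
        logits = self.out_conv(acc)
        return logits.reshape(n, h, w).sigmoid()

    __call__ = forward


def swin_segment_forward(image: np.ndarray, model: SwinSegmenter) -> np.ndarray:
    return _forward_numpy(image, model)


# --------------------------------------------------------------------------
# ensemble + ROI


def ensemble_segment(maps: list[np.ndarray], config: SegEnsembleConfig) -> np.ndarray:
    """Combine member probability maps and threshold to a binary mask.

    Score >= threshold counts as foreground.
    """
    if not maps:
        raise ValidationError("ensemble_segment needs at least one map")
    arrs = [np.asarray(m, dtype=np.float64) for m in maps]
    shape = arrs[0].shape
    for m in arrs:
        if m.shape != shape:
            raise ValidationError(f"probability map shape mismatch: {m.shape} vs {shape}")
    if config.combine_rule == "mean_probability":
        score = np.mean(arrs, axis=0)
    elif config.combine_rule == "max_probability":
        score = np.max(arrs, axis=0)
    else:
        w = np.asarray(config.member_weights, dtype=np.float64)
        if len(w) != len(arrs):
            raise ValidationError("member_weights length must match number of maps")
        score = np.tensordot(w, np.stack(arrs), axes=1)
    return (score >= config.threshold).astype(np.uint8)


def combine_probability_maps(maps: list[np.ndarray], config: SegEnsembleConfig) -> np.ndarray:
    """The continuous combined score (before thresholding)."""
    if config.combine_rule == "mean_probability":
        return np.mean([np.asarray(m, float) for m in maps], axis=0)
    if config.combine_rule == "max_probability":
        return np.max([np.asarray(m, float) for m in maps], axis=0)
    w = np.asarray(config.member_weights, dtype=np.float64)
    return np.tensordot(w, np.stack([np.asarray(m, float) for m in maps]), axes=1)


def extract_roi(image: np.ndarray, mask: np.ndarray, pad_fraction: float = 0.1,
                out_size: int | None = None) -> np.ndarray:
    """Zero the background, crop to the padded mask bounding box, and
    optionally resize; an empty mask passes the full image through."""
    from .preprocess import resize_and_normalize

    img = np.asarray(image, dtype=np.float32)
    m = np.asarray(mask)
    if m.shape != img.shape[:2]:
        raise ValidationError(f"mask shape {m.shape} != image spatial {img.shape[:2]}")
    ys, xs = np.nonzero(m)
    if len(ys) == 0:
        import logging
        logging.getLogger(__name__).warning(
            "extract_roi: empty mask, passing the full image through")
        out = img
    else:
        out = img * m[..., None]
        y0, y1 = ys.min(), ys.max() + 1
        x0, x1 = xs.min(), xs.max() + 1
        py = int(round((y1 - y0) * pad_fraction))
        px = int(round((x1 - x0) * pad_fraction))
        y0, y1 = max(0, y0 - py), min(img.shape[0], y1 + py)
        x0, x1 = max(0, x0 - px), min(img.shape[1], x1 + px)
        out = out[y0:y1, x0:x1]
    if out_size is not None:
        out = resize_and_normalize(out, out_size)
    return out


# --------------------------------------------------------------------------
# training


def dice_coefficient(pred: np.ndarray, truth: np.ndarray, eps: float = 1e-7) -> float:
    """2|A n B| / (|A| + |B|); empty-vs-empty counts as 1."""
    p = np.asarray(pred).astype(bool)
    t = np.asarray(truth).astype(bool)
    denom = p.sum() + t.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * np.logical_and(p, t).sum() / (denom + eps))


def _bce_dice_loss(prob: Tensor, mask: np.ndarray) -> Tensor:
    m = Tensor(mask.astype(np.float32))
    eps = 1e-6
    bce = -(m * (prob + eps).log() + (1.0 - m) * (1.0 - prob + eps).log()).mean()
    inter = (prob * m).sum()
    dice = 1.0 - (2.0 * inter + 1.0) / (prob.sum() + m.sum() + 1.0)
    return bce + dice


def build_segmenter(architecture: str, seed: int, *,
                    unet_config: UNetConfig | None = None,
                    swin_config: SwinSegConfig | None = None):
    rng = np.random.default_rng(seed)
    if architecture == "unet":
        return UNet(unet_config or UNetConfig(), rng)
    if architecture == "swin":
        return SwinSegmenter(swin_config or SwinSegConfig(), rng)
    raise ValidationError(f"unknown segmenter architecture '{architecture}'")


def train_segmenter(dataset: list[SyntheticSample], architecture: str,
                    train_config: TrainConfig, *,
                    unet_config: UNetConfig | None = None,
                    swin_config: SwinSegConfig | None = None,
                    model: Module | None = None):
    """Minimize pixelwise BCE + Dice loss with minibatch Adam/SGD.

    Returns ``(model, history)`` where history holds per-epoch train and
    validation losses plus validation Dice.  Deterministic given seeds.
    """
    if not dataset:
        raise ValidationError("train_segmenter: empty dataset")
    rng = np.random.default_rng(train_config.seed)
    if model is None:
        model = build_segmenter(architecture, train_config.seed,
                                unet_config=unet_config, swin_config=swin_config)
    images = np.stack([s.image for s in dataset]).transpose(0, 3, 1, 2)
    masks = np.stack([s.mask for s in dataset]).astype(np.float32)
    n = len(dataset)
    n_val = max(1, int(round(n * train_config.val_fraction))) if n > 1 else 0
    perm = rng.permutation(n)
    val_idx, tr_idx = perm[:n_val], perm[n_val:]
    if len(tr_idx) == 0:
        tr_idx = perm
    opt = make_optimizer(train_config.optimizer, model.parameters(),
                         train_config.learning_rate)
    history = {"train_loss": [], "val_loss": [], "val_dice": []}
    for _epoch in range(train_config.epochs):
        model.train()
        order = rng.permutation(len(tr_idx))
        losses = []
        for start in range(0, len(tr_idx), train_config.batch_size):
            idx = tr_idx[order[start:start + train_config.batch_size]]
            x = Tensor(images[idx])
            prob = model.forward(x)
            loss = _bce_dice_loss(prob, masks[idx])
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        history["train_loss"].append(float(np.mean(losses)))
        model.eval()
        if n_val:
            vloss, vdice = evaluate_segmenter(model, images[val_idx], masks[val_idx],
                                              batch_size=train_config.batch_size)
        else:
            vloss, vdice = history["train_loss"][-1], float("nan")
        history["val_loss"].append(vloss)
        history["val_dice"].append(vdice)
    model.eval()
    return model, history


def evaluate_segmenter(model: Module, images_nchw: np.ndarray, masks: np.ndarray,
                       batch_size: int = 32, threshold: float = 0.5):
    """Mean BCE+Dice loss and mean per-image Dice on a validation stack."""
    losses, dices = [], []
    for start in range(0, len(images_nchw), batch_size):
        x = Tensor(images_nchw[start:start + batch_size])
        m = masks[start:start + batch_size]
        prob = model.forward(x)
        losses.append(float(_bce_dice_loss(prob, m).data))
        for p_i, m_i in zip(prob.data, m):
            dices.append(dice_coefficient(p_i >= threshold, m_i))
    return float(np.mean(losses)), float(np.mean(dices))
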