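"""Hybrid convolution-attention classifiers.

``CoAtNet`` stacks convolutional stages (local texture/edge extraction)
before transformer stages (global context) and ends in global average
pooling and a softmax head.  ``EnhancedCoAtNet`` adds multiscale feature
aggregation — a convex, learnably weighted sum of feature maps from
several depths — an adaptive attention module that blends a
convolutional branch and a self-attention branch with free scalar
weights, dropout inside the transformer path, and batch normalization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._autograd import Tensor
from .nn import (BatchNorm2d, Conv2d, LayerNorm, Linear, Module, Parameter,
                 make_optimizer)
from .segmentation import TrainConfig
from .synthetic import SyntheticSample, ValidationError

# --------------------------------------------------------------------------
# configs


@dataclass
class CoAtNetConfig:
    stage_layout: tuple[str, ...] = ("conv", "conv", "transformer", "transformer")
    channels: tuple[int, ...] = (16, 32, 64, 64)
    blocks_per_stage: tuple[int, ...] = (1, 1, 1, 1)
    n_heads: int = 4
    n_classes: int = 10
    input_size: int = 64
    activation: str = "relu"    # relu | gelu

    def __post_init__(self):
        kinds = set(self.stage_layout)
        if not kinds <= {"conv", "transformer"}:
            raise ValidationError(f"unknown stage kind in {self.stage_layout}")
        first_t = next((i for i, k in enumerate(self.stage_layout)
                        if k == "transformer"), None)
        if first_t == 0:
            raise ValidationError(
                "at least one conv stage must precede the first transformer stage")
        if not (len(self.channels) == len(self.stage_layout) == len(self.blocks_per_stage)):
            raise ValidationError("stage_layout, channels, blocks_per_stage must align")
        total_down = 2 ** (1 + len(self.stage_layout))   # stem + one per stage
        if self.input_size % total_down:
            raise ValidationError(
                f"input_size {self.input_size} not divisible by total "
                f"downsampling {total_down}")
        if self.activation not in ("relu", "gelu"):
            raise ValidationError("activation must be relu or gelu")


@dataclass
class EnhancedCoAtNetConfig:
    base: CoAtNetConfig = field(default_factory=CoAtNetConfig)
    n_scales: int = 3
    alpha_init: tuple[float, ...] | None = None
    lambda_init: tuple[float, float] = (0.5, 0.5)
    dropout_rate: float = 0.1

    def __post_init__(self):
        if self.n_scales < 1:
            raise ValidationError("n_scales must be >= 1")
        if self.n_scales > len(self.base.stage_layout):
            raise ValidationError("n_scales exceeds the number of stages")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValidationError("dropout_rate must be in [0, 1)")
        if self.alpha_init is not None and len(self.alpha_init) != self.n_scales:
            raise ValidationError("alpha_init length must equal n_scales")


# --------------------------------------------------------------------------
# functional blocks (the op surface; the Modules below use the same math)


def _act(x: Tensor, kind: str) -> Tensor:
    return x.relu() if kind == "relu" else x.gelu()


def conv_block(features: np.ndarray, weight: np.ndarray, bias: np.ndarray,
               stride: int = 1, activation: str = "relu") -> np.ndarray:
    """Convolution + bias + activation on an (N, C, H, W) array."""
    x = Tensor(np.asarray(features, dtype=np.float32))
    w = Tensor(np.asarray(weight, dtype=np.float32))
    b = Tensor(np.asarray(bias, dtype=np.float32))
    k = w.shape[-1]
    return _act(x.conv2d(w, b, stride=stride, padding=k // 2), activation).data


def attention_block(tokens: np.ndarray, params: "GlobalAttention") -> np.ndarray:
    """Global multi-head self-attention over a flattened token list."""
    arr = np.asarray(tokens, dtype=np.float32)
    single = arr.ndim == 2
    if single:
        arr = arr[None]
    out = params.attend(Tensor(arr)).data
    return out[0] if single else out


def ffn_block(tokens: np.ndarray, w1, b1, w2, b2) -> np.ndarray:
    """linear -> ReLU -> linear with a residual connection."""
    x = Tensor(np.asarray(tokens, dtype=np.float32))
    h = x.linear(Tensor(np.asarray(w1, np.float32)), Tensor(np.asarray(b1, np.float32))).relu()
    out = h.linear(Tensor(np.asarray(w2, np.float32)), Tensor(np.asarray(b2, np.float32)))
    return (x + out).data


def multiscale_aggregate(feature_list, alpha_logits, target_shape,
                         projections=None) -> np.ndarray:
    """Convex multiscale fusion: resize every map to ``target_shape``,
    optionally 1x1-project to a common width, then sum weighted by
    ``softmax(alpha_logits)``."""
    if len(feature_list) == 0:
        raise ValidationError("multiscale_aggregate: empty feature list")
    logits = np.asarray(alpha_logits, dtype=np.float64)
    if logits.shape != (len(feature_list),):
        raise ValidationError("alpha_logits must have one entry per scale")
    ex = np.exp(logits - logits.max())
    alpha = ex / ex.sum()
    th, tw = target_shape
    acc = None
    for i, f in enumerate(feature_list):
        t = Tensor(np.asarray(f, dtype=np.float32))
        if projections is not None:
            t = projections[i](t)
        if t.shape[-2:] != (th, tw):
            t = t.upsample_bilinear(th, tw)
        term = t * float(alpha[i])
        acc = term if acc is None else acc + term
    return acc.data


def adaptive_attention(features: np.ndarray, lambda1: float, lambda2: float,
                       conv_branch, attention_branch) -> np.ndarray:
    """lambda1 * Conv(x) + lambda2 * SelfAttention(x); the scalars are
    free (unconstrained) learnable weights."""
    x = Tensor(np.asarray(features, dtype=np.float32))
    return (conv_branch(x) * float(lambda1) + attention_branch(x) * float(lambda2)).data


def batch_normalize(features: np.ndarray, gamma: np.ndarray, beta_shift: np.ndarray,
                    eps: float = 1e-5, mode: str = "train",
                    running_stats: tuple[np.ndarray, np.ndarray] | None = None) -> np.ndarray:
    """Per-channel standardization then affine scale/shift on (N, C, H, W)."""
    x = Tensor(np.asarray(features, dtype=np.float32))
    g = Tensor(np.asarray(gamma, np.float32))
    b = Tensor(np.asarray(beta_shift, np.float32))
    c = x.shape[1]
    if running_stats is None:
        running_stats = (np.zeros(c, np.float32), np.ones(c, np.float32))
    g.requires_grad = b.requires_grad = True   # reuse the fused op
    return x.batch_norm(g, b, running_stats[0], running_stats[1],
                        training=(mode == "train"), eps=eps).data


def apply_dropout(features: np.ndarray, rate: float, mode: str = "train",
                  seed: int = 0) -> np.ndarray:
    """Inverted dropout; identity at inference."""
    x = Tensor(np.asarray(features, dtype=np.float32))
    rng = np.random.default_rng(seed)
    return x.dropout(rate, rng, training=(mode == "train")).data


# --------------------------------------------------------------------------
# modules


class GlobalAttention(Module):
    """Multi-head scaled dot-product attention over all tokens (one window
    covering the whole grid) with residual + post-LN, then an FFN block."""

    def __init__(self, dim: int, n_heads: int, rng: np.random.Generator,
                 mlp_ratio: int = 2):
        super().__init__()
        if dim % n_heads:
            raise ValidationError(f"dim {dim} not divisible by n_heads {n_heads}")
        if dim // n_heads == 0:
            raise ValidationError("head dimension must be positive")
        self.n_heads = n_heads
        self.q = Linear(dim, dim, rng)
        self.k = Linear(dim, dim, rng)
        self.v = Linear(dim, dim, rng)
        self.proj = Linear(dim, dim, rng)
        self.norm1 = LayerNorm(dim)
        self.norm2 = LayerNorm(dim)
        self.fc1 = Linear(dim, dim * mlp_ratio, rng)
        self.fc2 = Linear(dim * mlp_ratio, dim, rng)
        self.dropout_rate = 0.0
        self._rng = np.random.default_rng(int(rng.integers(2 ** 31)))

    def attend(self, x: Tensor) -> Tensor:
        """Pure attention: x (B, T, C) -> (B, T, C), no residual/norm."""
        b, T, c = x.shape
        hd = c // self.n_heads

        def heads(z: Tensor) -> Tensor:
            return z.reshape(b, T, self.n_heads, hd).transpose(0, 2, 1, 3)

        q, k, v = heads(self.q(x)), heads(self.k(x)), heads(self.v(x))
        attn = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(hd))
        out = attn.softmax(axis=-1) @ v
        return self.proj(out.transpose(0, 2, 1, 3).reshape(b, T, c))

    def __call__(self, x: Tensor) -> Tensor:
        a = self.attend(x)
        if self.dropout_rate > 0:
            a = a.dropout(self.dropout_rate, self._rng, self.training)
        y = self.norm1(x + a)
        h = self.fc2(self.fc1(y).relu())
        return self.norm2(y + h)


class CoAtNet(Module):
    """Conv stages then transformer stages; GAP + linear + softmax head.

    A stride-2 stem plus one stride-2 downsample per stage halve the
    resolution; per-stage feature maps are kept for multiscale reuse
    and Grad-CAM.
    """

    def __init__(self, config: CoAtNetConfig, rng: np.random.Generator):
        super().__init__()
        self.config = config
        self.stem = Conv2d(3, config.channels[0], 3, rng, stride=2)
        self.stem_bn = BatchNorm2d(config.channels[0])
        self.downs = []
        self.down_bns = []
        self.stage_blocks = []
        c_prev = config.channels[0]
        for kind, c, nb in zip(config.stage_layout, config.channels,
                               config.blocks_per_stage):
            self.downs.append(Conv2d(c_prev, c, 3, rng, stride=2))
            self.down_bns.append(BatchNorm2d(c))
            blocks = []
            for _ in range(nb):
                if kind == "conv":
                    blocks.append(Conv2d(c, c, 3, rng))
                else:
                    blocks.append(GlobalAttention(c, config.n_heads, rng))
            self.stage_blocks.append(blocks)
            c_prev = c
        self.head = Linear(c_prev, config.n_classes, rng)
        self._features: dict[str, Tensor] = {}

    def trunk(self, x: Tensor) -> list[Tensor]:
        """Forward through stem + stages; returns per-stage feature maps
        (NCHW) and caches them for Grad-CAM."""
        self._features = {}
        x = _act(self.stem_bn(self.stem(x)), self.config.activation)
        self._features["stem"] = x
        outs = []
        for si, (kind, blocks) in enumerate(zip(self.config.stage_layout,
                                                self.stage_blocks)):
            x = _act(self.down_bns[si](self.downs[si](x)), self.config.activation)
            if kind == "conv":
                for blk in blocks:
                    x = x + _act(blk(x), self.config.activation)
            else:
                n, c, h, w = x.shape
                t = x.reshape(n, c, h * w).transpose(0, 2, 1)
                for blk in blocks:
                    t = blk(t)
                x = t.transpose(0, 2, 1).reshape(n, c, h, w)
            self._features[f"stage{si}"] = x
            outs.append(x)
        return outs

    def logits(self, x: Tensor) -> Tensor:
        feats = self.trunk(x)
        pooled = feats[-1].mean(axis=(2, 3))
        return self.head(pooled)

    def forward(self, x: Tensor) -> Tensor:
        """(N, 3, H, W) -> class probabilities (N, K)."""
        return self.logits(x).softmax(axis=-1)

    __call__ = forward

    @property
    def feature_layers(self) -> list[str]:
        return ["stem"] + [f"stage{i}" for i in range(len(self.config.stage_layout))]

    @property
    def default_cam_layer(self) -> str:
        convs = [i for i, k in enumerate(self.config.stage_layout) if k == "conv"]
        return f"stage{convs[-1]}"


class EnhancedCoAtNet(Module):
    """CoAtNet trunk + multiscale aggregation + adaptive attention +
    dropout + batch normalization, then the softmax head."""

    def __init__(self, config: EnhancedCoAtNetConfig, rng: np.random.Generator):
        super().__init__()
        self.config = config
        self.base = CoAtNet(config.base, rng)
        for blocks in self.base.stage_blocks:
            for blk in blocks:
                if isinstance(blk, GlobalAttention):
                    blk.dropout_rate = config.dropout_rate
        n = config.n_scales
        ch = config.base.channels
        self.scale_channels = ch[-n:]
        self.common = ch[-1]
        self.scale_projs = [Conv2d(c, self.common, 1, rng, padding=0)
                            for c in self.scale_channels]
        init = config.alpha_init if config.alpha_init is not None else [0.0] * n
        self.alpha_logits = Parameter(np.asarray(init, dtype=np.float32))
        self.lambda1 = Parameter(np.asarray(config.lambda_init[0], dtype=np.float32))
        self.lambda2 = Parameter(np.asarray(config.lambda_init[1], dtype=np.float32))
        self.conv_branch = Conv2d(self.common, self.common, 3, rng)
        self.attn_branch = GlobalAttention(self.common, config.base.n_heads, rng)
        self.bn = BatchNorm2d(self.common)
        self.head = Linear(self.common, config.base.n_classes, rng)
        self._drop_rng = np.random.default_rng(int(rng.integers(2 ** 31)))
        self._features: dict[str, Tensor] = {}

    def logits(self, x: Tensor) -> Tensor:
        feats = self.base.trunk(x)
        used = feats[-self.config.n_scales:]
        th, tw = used[-1].shape[-2:]
        alpha = self.alpha_logits.softmax(axis=0)
        acc = None
        for i, f in enumerate(used):
            t = self.scale_projs[i](f)
            if t.shape[-2:] != (th, tw):
                t = t.upsample_bilinear(th, tw)
            term = t * alpha[i]
            acc = term if acc is None else acc + term
        self._features = dict(self.base._features)
        self._features["aggregated"] = acc
        n, c, h, w = acc.shape
        tok = acc.reshape(n, c, h * w).transpose(0, 2, 1)
        attn_out = self.attn_branch.attend(tok).transpose(0, 2, 1).reshape(n, c, h, w)
        fused = self.conv_branch(acc) * self.lambda1 + attn_out * self.lambda2
        fused = fused.dropout(self.config.dropout_rate, self._drop_rng, self.training)
        fused = self.bn(fused)
        self._features["refined"] = fused
        pooled = fused.mean(axis=(2, 3))
        return self.head(pooled)

    def forward(self, x: Tensor) -> Tensor:
        return self.logits(x).softmax(axis=-1)

    __call__ = forward

    @property
    def feature_layers(self) -> list[str]:
        return self.base.feature_layers + ["aggregated", "refined"]

    @property
    def default_cam_layer(self) -> str:
        return "aggregated"


def coatnet_forward(image: np.ndarray, model: CoAtNet) -> np.ndarray:
    """(H, W, 3) or (N, H, W, 3) image(s) -> class probabilities
    (inference mode)."""
    model.eval()
    arr = np.asarray(image, dtype=np.float32)
    single = arr.ndim == 3
    if single:
        arr = arr[None]
    out = model.forward(Tensor(arr.transpose(0, 3, 1, 2))).data
    return out[0] if single else out


enhanced_coatnet_forward = coatnet_forward


# --------------------------------------------------------------------------
# training


def build_classifier(architecture: str, seed: int, *,
                     coatnet_config: CoAtNetConfig | None = None,
                     enhanced_config: EnhancedCoAtNetConfig | None = None):
    rng = np.random.default_rng(seed)
    if architecture == "coatnet":
        return CoAtNet(coatnet_config or CoAtNetConfig(), rng)
    if architecture in ("enhanced", "enhanced_coatnet"):
        return EnhancedCoAtNet(enhanced_config or EnhancedCoAtNetConfig(), rng)
    raise ValidationError(f"unknown classifier architecture '{architecture}'")


def cross_entropy(probs: Tensor, labels: np.ndarray) -> Tensor:
    n = probs.shape[0]
    picked = probs[np.arange(n), np.asarray(labels)]
    return -((picked + 1e-9).log().mean())


def train_classifier(dataset: list[SyntheticSample], architecture: str,
                     train_config: TrainConfig, *,
                     coatnet_config: CoAtNetConfig | None = None,
                     enhanced_config: EnhancedCoAtNetConfig | None = None,
                     model: Module | None = None,
                     images: np.ndarray | None = None,
                     labels: np.ndarray | None = None):
    """Minimize cross-entropy with minibatch Adam/SGD.

    Input is either a list of samples or pre-built ``images`` (NHWC) +
    ``labels`` arrays (e.g. ROI-extracted crops).  Returns ``(model,
    history)`` with per-epoch train loss/accuracy and validation
    loss/accuracy.
    """
    if images is None:
        if not dataset:
            raise ValidationError("train_classifier: empty dataset")
        images = np.stack([s.image for s in dataset])
        labels = np.asarray([s.label for s in dataset])
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValidationError("train_classifier needs at least two classes")
    rng = np.random.default_rng(train_config.seed)
    if model is None:
        model = build_classifier(architecture, train_config.seed,
                                 coatnet_config=coatnet_config,
                                 enhanced_config=enhanced_config)
    x_all = images.transpose(0, 3, 1, 2).astype(np.float32)
    n = len(labels)
    n_val = max(1, int(round(n * train_config.val_fraction))) if n > 1 else 0
    perm = rng.permutation(n)
    val_idx, tr_idx = perm[:n_val], perm[n_val:]
    if len(tr_idx) == 0:
        tr_idx = perm
    opt = make_optimizer(train_config.optimizer, model.parameters(),
                         train_config.learning_rate)
    history = {"train_loss": [], "train_acc": [], "val_loss": [], "val_acc": []}
    for _epoch in range(train_config.epochs):
        model.train()
        order = rng.permutation(len(tr_idx))
        losses, correct = [], 0
        for start in range(0, len(tr_idx), train_config.batch_size):
            idx = tr_idx[order[start:start + train_config.batch_size]]
            if len(idx) < 2 and len(tr_idx) > 2:
                continue    # batch-norm needs >= 2 samples in training mode
            probs = model.forward(Tensor(x_all[idx]))
            loss = cross_entropy(probs, labels[idx])
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
            correct += int((probs.data.argmax(1) == labels[idx]).sum())
        history["train_loss"].append(float(np.mean(losses)))
        history["train_acc"].append(correct / len(tr_idx))
        model.eval()
        if n_val:
            vp = predict_probabilities(model, images[val_idx],
                                       batch_size=train_config.batch_size)
            vl = float(cross_entropy(Tensor(vp), labels[val_idx]).data)
            va = float((vp.argmax(1) == labels[val_idx]).mean())
        else:
            vl, va = history["train_loss"][-1], history["train_acc"][-1]
        history["val_loss"].append(vl)
        history["val_acc"].append(va)
    model.eval()
    return model, history


def predict_probabilities(model: Module, images_nhwc: np.ndarray,
                          batch_size: int = 32) -> np.ndarray:
    """Row-stochastic (n, K) probability matrix for a stack of images."""
    model.eval()
    x = np.asarray(images_nhwc, dtype=np.float32).transpose(0, 3, 1, 2)
    outs = []
    for start in range(0, len(x), batch_size):
        outs.append(model.forward(Tensor(x[start:start + batch_size])).data)
    return np.concatenate(outs, axis=0)
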