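"""Minimal reverse-mode automatic differentiation on numpy arrays.

A :class:`Tensor` wraps an ``ndarray`` and records, for every operation,
a closure that propagates gradients to its parents.  ``Tensor.backward``
runs the tape in reverse topological order.  The op set is exactly what
the networks in this package need: broadcast arithmetic, (batched)
matmul, fused linear / softmax / layer-norm / batch-norm, im2col-based
2-D convolution and its transpose, max pooling, bilinear resampling and
a handful of shape ops.  Everything is float32 by default and fully
deterministic given seeded inputs.
"""

from __future__ import annotations

import numpy as np
from scipy import special as _sp_special

__all__ = ["Tensor", "concatenate"]

_DTYPE = np.float32


def _as_array(x) -> np.ndarray:
    if isinstance(x, np.ndarray):
        return x.astype(_DTYPE, copy=False)
    return np.asarray(x, dtype=_DTYPE)


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (the reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    nd = grad.ndim - len(shape)
    if nd > 0:
        grad = grad.sum(axis=tuple(range(nd)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = _as_array(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # -- construction helpers -------------------------------------------------

    @staticmethod
    def _make(data, parents, backward):
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accum(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = grad.astype(_DTYPE, copy=True)
        else:
            self.grad += grad

    # -- basic properties -----------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def zero_grad(self) -> None:
        self.grad = None

    # -- autodiff driver ------------------------------------------------------

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        self._accum(_as_array(grad))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- arithmetic -----------------------------------------------------------

    @staticmethod
    def _coerce(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other):
        other = self._coerce(other)
        out_data = self.data + other.data

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        return Tensor._make(out_data, (self, other), bw)

    __radd__ = __add__

    def __neg__(self):
        def bw(g):
            self._accum(-g)

        return Tensor._make(-self.data, (self,), bw)

    def __sub__(self, other):
        return self + (-self._coerce(other))

    def __rsub__(self, other):
        return self._coerce(other) + (-self)

    def __mul__(self, other):
        other = self._coerce(other)
        out_data = self.data * other.data

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        return Tensor._make(out_data, (self, other), bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._coerce(other)
        out_data = self.data / other.data

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accum(
                    _unbroadcast(-g * self.data / (other.data ** 2), other.data.shape)
                )

        return Tensor._make(out_data, (self, other), bw)

    def __pow__(self, exponent: float):
        out_data = self.data ** exponent

        def bw(g):
            self._accum(g * exponent * self.data ** (exponent - 1))

        return Tensor._make(out_data, (self,), bw)

    def __matmul__(self, other):
        """Matmul; supports 2-D weights against (..., d) inputs and
        same-rank batched operands."""
        other = self._coerce(other)
        a, b = self.data, other.data
        out_data = a @ b

        def bw(g):
            if self.requires_grad:
                if b.ndim == 2:
                    self._accum(g @ b.T)
                else:
                    self._accum(_unbroadcast(g @ np.swapaxes(b, -1, -2), a.shape))
            if other.requires_grad:
                if b.ndim == 2 and a.ndim > 2:
                    other._accum(a.reshape(-1, a.shape[-1]).T @ g.reshape(-1, g.shape[-1]))
                else:
                    other._accum(_unbroadcast(np.swapaxes(a, -1, -2) @ g, b.shape))

        return Tensor._make(out_data, (self, other), bw)

    # -- elementwise nonlinearities -------------------------------------------

    def relu(self):
        mask = self.data > 0
        out_data = np.where(mask, self.data, 0)

        def bw(g):
            self._accum(g * mask)

        return Tensor._make(out_data, (self,), bw)

    def gelu(self):
        x = self.data.astype(np.float64)
        phi = 0.5 * (1.0 + _sp_special.erf(x / np.sqrt(2.0)))
        pdf = np.exp(-0.5 * x * x) / np.sqrt(2.0 * np.pi)
        out_data = (x * phi).astype(_DTYPE)
        deriv = (phi + x * pdf).astype(_DTYPE)

        def bw(g):
            self._accum(g * deriv)

        return Tensor._make(out_data, (self,), bw)

    def sigmoid(self):
        out_data = _sp_special.expit(self.data)

        def bw(g):
            self._accum(g * out_data * (1.0 - out_data))

        return Tensor._make(out_data, (self,), bw)

    def exp(self):
        out_data = np.exp(self.data)

        def bw(g):
            self._accum(g * out_data)

        return Tensor._make(out_data, (self,), bw)

    def log(self):
        def bw(g):
            self._accum(g / self.data)

        return Tensor._make(np.log(self.data), (self,), bw)

    # -- reductions -----------------------------------------------------------

    def sum(self, axis=None, keepdims=False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def bw(g):
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape).copy())
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape).copy())

        return Tensor._make(out_data, (self,), bw)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in np.atleast_1d(axis)]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    # -- shape ops ------------------------------------------------------------

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.data.shape

        def bw(g):
            self._accum(g.reshape(old))

        return Tensor._make(self.data.reshape(shape), (self,), bw)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)

        def bw(g):
            self._accum(g.transpose(inv))

        return Tensor._make(self.data.transpose(axes), (self,), bw)

    def __getitem__(self, idx):
        out_data = self.data[idx]

        def bw(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            self._accum(full)

        return Tensor._make(out_data, (self,), bw)

    def pad2d(self, pad_h: int, pad_w: int):
        """Zero-pad the last two axes symmetrically."""
        widths = [(0, 0)] * (self.data.ndim - 2) + [(pad_h, pad_h), (pad_w, pad_w)]
        out_data = np.pad(self.data, widths)
        sl = tuple(
            [slice(None)] * (self.data.ndim - 2)
            + [slice(pad_h, out_data.shape[-2] - pad_h) if pad_h else slice(None),
               slice(pad_w, out_data.shape[-1] - pad_w) if pad_w else slice(None)]
        )

        def bw(g):
            self._accum(g[sl])

        return Tensor._make(out_data, (self,), bw)

    def roll(self, shift, axis):
        neg = tuple(-s for s in np.atleast_1d(shift))

        def bw(g):
            self._accum(np.roll(g, neg, axis=axis))

        return Tensor._make(np.roll(self.data, shift, axis=axis), (self,), bw)

    def dilate2d(self, stride: int):
        """Insert ``stride - 1`` zeros between entries of the last two axes."""
        if stride == 1:
            return self
        *lead, h, w = self.data.shape
        out_data = np.zeros((*lead, (h - 1) * stride + 1, (w - 1) * stride + 1), dtype=_DTYPE)
        out_data[..., ::stride, ::stride] = self.data

        def bw(g):
            self._accum(np.ascontiguousarray(g[..., ::stride, ::stride]))

        return Tensor._make(out_data, (self,), bw)

    # -- fused ops ------------------------------------------------------------

    def linear(self, weight: "Tensor", bias: "Tensor | None" = None):
        """``x @ W + b`` for x of shape (..., d_in), W (d_in, d_out)."""
        out = self @ weight
        if bias is not None:
            out = out + bias
        return out

    def softmax(self, axis: int = -1):
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        out_data = e / e.sum(axis=axis, keepdims=True)

        def bw(g):
            dot = (g * out_data).sum(axis=axis, keepdims=True)
            self._accum(out_data * (g - dot))

        return Tensor._make(out_data, (self,), bw)

    def layer_norm(self, gamma: "Tensor", beta: "Tensor", eps: float = 1e-5):
        """Normalize over the last axis, then affine scale/shift."""
        x = self.data
        mu = x.mean(axis=-1, keepdims=True)
        var = x.var(axis=-1, keepdims=True)
        inv = 1.0 / np.sqrt(var + eps)
        xhat = (x - mu) * inv
        out_data = gamma.data * xhat + beta.data

        def bw(g):
            n = x.shape[-1]
            if gamma.requires_grad:
                red = tuple(range(g.ndim - 1))
                gamma._accum((g * xhat).sum(axis=red))
            if beta.requires_grad:
                red = tuple(range(g.ndim - 1))
                beta._accum(g.sum(axis=red))
            if self.requires_grad:
                gh = g * gamma.data
                term = gh - gh.mean(axis=-1, keepdims=True) - xhat * (
                    (gh * xhat).mean(axis=-1, keepdims=True)
                )
                self._accum(term * inv)

        return Tensor._make(out_data, (self, gamma, beta), bw)

    def conv2d(self, weight: "Tensor", bias: "Tensor | None" = None,
               stride: int = 1, padding: int = 0):
        """2-D cross-correlation, NCHW layout, via im2col + matmul.

        weight: (C_out, C_in, kh, kw)
        """
        x = self.data
        w = weight.data
        n, c_in, h, wdt = x.shape
        c_out, c_in2, kh, kw = w.shape
        if c_in != c_in2:
            raise ValueError(f"conv2d channel mismatch: input {c_in}, kernel {c_in2}")
        if padding:
            xp = np.pad(x, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
        else:
            xp = x
        hp, wp = xp.shape[2], xp.shape[3]
        oh = (hp - kh) // stride + 1
        ow = (wp - kw) // stride + 1
        win = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
        win = win[:, :, ::stride, ::stride]          # (n, c_in, oh, ow, kh, kw)
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * oh * ow, c_in * kh * kw)
        wflat = w.reshape(c_out, -1)
        out = cols @ wflat.T                          # (n*oh*ow, c_out)
        out_data = out.reshape(n, oh, ow, c_out).transpose(0, 3, 1, 2)
        if bias is not None:
            out_data = out_data + bias.data.reshape(1, c_out, 1, 1)

        def bw(g):
            g2 = g.transpose(0, 2, 3, 1).reshape(n * oh * ow, c_out)
            if bias is not None and bias.requires_grad:
                bias._accum(g2.sum(axis=0))
            if weight.requires_grad:
                weight._accum((g2.T @ cols).reshape(w.shape))
            if self.requires_grad:
                gcols = (g2 @ wflat).reshape(n, oh, ow, c_in, kh, kw)
                gxp = np.zeros((n, c_in, hp, wp), dtype=_DTYPE)
                for di in range(kh):
                    for dj in range(kw):
                        gxp[:, :, di:di + oh * stride:stride,
                            dj:dj + ow * stride:stride] += gcols[:, :, :, :, di, dj].transpose(0, 3, 1, 2)
                if padding:
                    gxp = gxp[:, :, padding:hp - padding, padding:wp - padding]
                self._accum(gxp)

        parents = (self, weight) if bias is None else (self, weight, bias)
        return Tensor._make(out_data, parents, bw)

    def conv_transpose2d(self, weight: "Tensor", bias: "Tensor | None" = None,
                         stride: int = 2):
        """Transposed convolution (fractional stride): zero-dilate the input
        then convolve with the spatially flipped kernel.

        weight: (C_in, C_out, kh, kw); output spatial size = stride*(H-1)+kh.
        """
        c_in, c_out, kh, kw = weight.data.shape
        flipped = weight[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)  # (C_out, C_in, kh, kw)
        dil = self.dilate2d(stride)
        return dil.conv2d(flipped, bias, stride=1, padding=max(kh, kw) - 1)

    def maxpool2d(self, k: int = 2):
        """Non-overlapping k x k max pooling on NCHW."""
        n, c, h, w = self.data.shape
        if h % k or w % k:
            raise ValueError(f"maxpool2d: spatial dims ({h},{w}) not divisible by {k}")
        view = self.data.reshape(n, c, h // k, k, w // k, k)
        patches = view.transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h // k, w // k, k * k)
        arg = patches.argmax(axis=-1)
        out_data = np.take_along_axis(patches, arg[..., None], axis=-1)[..., 0]

        def bw(g):
            gpatch = np.zeros_like(patches)
            np.put_along_axis(gpatch, arg[..., None], g[..., None], axis=-1)
            gx = gpatch.reshape(n, c, h // k, w // k, k, k).transpose(0, 1, 2, 4, 3, 5)
            self._accum(gx.reshape(n, c, h, w))

        return Tensor._make(out_data, (self,), bw)

    def batch_norm(self, gamma: "Tensor", beta: "Tensor", running_mean: np.ndarray,
                   running_var: np.ndarray, training: bool, momentum: float = 0.1,
                   eps: float = 1e-5):
        """Per-channel batch normalization on NCHW (stats over N, H, W).

        Mutates ``running_mean``/``running_var`` in place during training.
        """
        x = self.data
        axes = (0, 2, 3)
        shape = (1, x.shape[1], 1, 1)
        if training:
            if x.shape[0] < 2:
                raise ValueError("batch_norm in training mode needs batch size >= 2")
            mu = x.mean(axis=axes)
            var = x.var(axis=axes)
            running_mean *= 1.0 - momentum
            running_mean += momentum * mu
            running_var *= 1.0 - momentum
            running_var += momentum * var
        else:
            mu, var = running_mean, running_var
        inv = 1.0 / np.sqrt(var + eps)
        xhat = (x - mu.reshape(shape)) * inv.reshape(shape)
        out_data = gamma.data.reshape(shape) * xhat + beta.data.reshape(shape)
        m = x.shape[0] * x.shape[2] * x.shape[3]

        def bw(g):
            if gamma.requires_grad:
                gamma._accum((g * xhat).sum(axis=axes))
            if beta.requires_grad:
                beta._accum(g.sum(axis=axes))
            if self.requires_grad:
                gh = g * gamma.data.reshape(shape)
                if training:
                    term = gh - gh.mean(axis=axes, keepdims=True) - xhat * (
                        (gh * xhat).mean(axis=axes, keepdims=True)
                    )
                    self._accum(term * inv.reshape(shape))
                else:
                    self._accum(gh * inv.reshape(shape))

        return Tensor._make(out_data, (self, gamma, beta), bw)

    def dropout(self, rate: float, rng: np.random.Generator, training: bool):
        """Inverted dropout: identity at inference; survivors scaled 1/(1-rate)."""
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"dropout rate must be in [0, 1), got {rate}")
        if not training or rate == 0.0:
            return self
        mask = (rng.random(self.data.shape) >= rate).astype(_DTYPE) / (1.0 - rate)

        def bw(g):
            self._accum(g * mask)

        return Tensor._make(self.data * mask, (self,), bw)

    def upsample_bilinear(self, out_h: int, out_w: int):
        """Bilinear resize of NCHW feature maps (half-pixel centers)."""
        n, c, h, w = self.data.shape
        iy, wy0, wy1, iy1 = _lin_coeffs(h, out_h)
        ix, wx0, wx1, ix1 = _lin_coeffs(w, out_w)
        x = self.data
        top = x[:, :, iy][:, :, :, ix] * (wy0[:, None] * wx0[None, :]) \
            + x[:, :, iy][:, :, :, ix1] * (wy0[:, None] * wx1[None, :])
        bot = x[:, :, iy1][:, :, :, ix] * (wy1[:, None] * wx0[None, :]) \
            + x[:, :, iy1][:, :, :, ix1] * (wy1[:, None] * wx1[None, :])
        out_data = (top + bot).astype(_DTYPE)

        def bw(g):
            gx = np.zeros_like(x)
            for wy, rows in ((wy0, iy), (wy1, iy1)):
                for wx, colsi in ((wx0, ix), (wx1, ix1)):
                    contrib = g * (wy[:, None] * wx[None, :])
                    np.add.at(gx, (slice(None), slice(None), rows[:, None], colsi[None, :]), contrib)
            self._accum(gx)

        return Tensor._make(out_data, (self,), bw)


def _lin_coeffs(in_size: int, out_size: int):
    """Gather indices and weights for 1-D linear interpolation."""
    pos = (np.arange(out_size) + 0.5) * in_size / out_size - 0.5
    pos = np.clip(pos, 0, in_size - 1)
    i0 = np.floor(pos).astype(np.intp)
    i1 = np.minimum(i0 + 1, in_size - 1)
    w1 = (pos - i0).astype(_DTYPE)
    w0 = (1.0 - w1).astype(_DTYPE)
    return i0, w0, w1, i1


def concatenate(tensors: list[Tensor], axis: int) -> Tensor:
    datas = [t.data for t in tensors]
    out_data = np.concatenate(datas, axis=axis)
    sizes = [d.shape[axis] for d in datas]
    splits = np.cumsum(sizes)[:-1]

    def bw(g):
        parts = np.split(g, splits, axis=axis)
        for t, p in zip(tensors, parts):
            if t.requires_grad:
                t._accum(np.ascontiguousarray(p))

    return Tensor._make(out_data, tuple(tensors), bw)
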