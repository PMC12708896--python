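"""Neural-network building blocks over the autodiff core.

Layers hold :class:`Parameter` tensors; :class:`Module` collects them
recursively so optimizers and checkpointing can enumerate named weights.
Initialization draws from a caller-supplied ``numpy.random.Generator``
so entire models are reproducible from one seed.
"""

from __future__ import annotations

import numpy as np

from ._autograd import Tensor

__all__ = [
    "Parameter", "Module", "Linear", "Conv2d", "ConvTranspose2d",
    "LayerNorm", "BatchNorm2d", "Adam", "SGD",
]


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Base class: recursive parameter discovery plus a train/eval flag."""

    def __init__(self):
        self.training = True

    @staticmethod
    def _walk(value, key):
        """Yield (key, leaf) pairs for Parameters and Modules, recursing
        through arbitrarily nested lists/tuples."""
        if isinstance(value, (Parameter, Module)):
            yield key, value
        elif isinstance(value, (list, tuple)):
            for i, item in enumerate(value):
                yield from Module._walk(item, f"{key}.{i}")

    def modules(self):
        for value in self.__dict__.values():
            for _, leaf in Module._walk(value, ""):
                if isinstance(leaf, Module):
                    yield leaf
                    yield from leaf.modules()

    def named_parameters(self, prefix: str = ""):
        for name, value in self.__dict__.items():
            for key, leaf in Module._walk(value, f"{prefix}{name}"):
                if isinstance(leaf, Parameter):
                    yield key, leaf
                elif isinstance(leaf, Module):
                    yield from leaf.named_parameters(f"{key}.")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def train(self):
        self.training = True
        for m in self.modules():
            m.training = True
        return self

    def eval(self):
        self.training = False
        for m in self.modules():
            m.training = False
        return self

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        for name, buf in self.named_buffers():
            state[name] = buf.copy()
        return state

    def named_buffers(self, prefix: str = ""):
        for name, value in self.__dict__.items():
            key = f"{prefix}{name}"
            if isinstance(value, np.ndarray) and name.startswith("running_"):
                yield key, value
                continue
            for sub, leaf in Module._walk(value, key):
                if isinstance(leaf, Module):
                    yield from leaf.named_buffers(f"{sub}.")

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        bufs = dict(self.named_buffers())
        for name, arr in state.items():
            if name in params:
                if params[name].data.shape != arr.shape:
                    raise ValueError(f"shape mismatch for {name}")
                params[name].data = arr.astype(np.float32).copy()
            elif name in bufs:
                bufs[name][...] = arr
            else:
                raise KeyError(f"unknown parameter {name}")


def _he(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(np.float32)


def _glorot(rng: np.random.Generator, shape, fan_in: int, fan_out: int) -> np.ndarray:
    lim = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-lim, lim, size=shape).astype(np.float32)


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator, bias: bool = True):
        super().__init__()
        self.weight = Parameter(_glorot(rng, (d_in, d_out), d_in, d_out))
        self.bias = Parameter(np.zeros(d_out, dtype=np.float32)) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        return x.linear(self.weight, self.bias)


class Conv2d(Module):
    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator,
                 stride: int = 1, padding: int | None = None):
        super().__init__()
        self.stride = stride
        self.padding = k // 2 if padding is None else padding
        self.weight = Parameter(_he(rng, (c_out, c_in, k, k), c_in * k * k))
        self.bias = Parameter(np.zeros(c_out, dtype=np.float32))

    def __call__(self, x: Tensor) -> Tensor:
        return x.conv2d(self.weight, self.bias, stride=self.stride, padding=self.padding)


class ConvTranspose2d(Module):
    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator, stride: int = 2):
        super().__init__()
        self.stride = stride
        self.weight = Parameter(_he(rng, (c_in, c_out, k, k), c_in * k * k))
        self.bias = Parameter(np.zeros(c_out, dtype=np.float32))

    def __call__(self, x: Tensor) -> Tensor:
        out = x.conv_transpose2d(self.weight, None, stride=self.stride)
        return out + self.bias.reshape(1, -1, 1, 1)


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        super().__init__()
        self.eps = eps
        self.gamma = Parameter(np.ones(dim, dtype=np.float32))
        self.beta = Parameter(np.zeros(dim, dtype=np.float32))

    def __call__(self, x: Tensor) -> Tensor:
        return x.layer_norm(self.gamma, self.beta, self.eps)


class BatchNorm2d(Module):
    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.gamma = Parameter(np.ones(channels, dtype=np.float32))
        self.beta = Parameter(np.zeros(channels, dtype=np.float32))
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)

    def __call__(self, x: Tensor) -> Tensor:
        return x.batch_norm(self.gamma, self.beta, self.running_mean,
                            self.running_var, self.training, self.momentum, self.eps)


class Adam:
    """Adam with bias-corrected first/second moments."""

    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None


class SGD:
    def __init__(self, params, lr: float = 0.01):
        self.params = list(params)
        self.lr = lr

    def step(self):
        for p in self.params:
            if p.grad is not None:
                p.data -= self.lr * p.grad

    def zero_grad(self):
        for p in self.params:
            p.grad = None


def make_optimizer(name: str, params, lr: float):
    name = name.lower()
    if name == "adam":
        return Adam(params, lr=lr)
    if name == "sgd":
        return SGD(params, lr=lr)
    raise ValueError(f"unknown optimizer '{name}' (expected adam or sgd)")
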