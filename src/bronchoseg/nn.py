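"""Neural-network layers, parameter management and AdamW on the autodiff engine.

Layers operate on single images laid out channels-first ``(C, H, W)`` or on
token matrices ``(N, C)`` — the optimization batch size is 1 throughout, which
matches the training regime the model is designed for.
"""

from __future__ import annotations

import math

import numpy as np

from .autodiff import Tensor, conv2d, conv_transpose2d

__all__ = [
    "Parameter", "Module", "Linear", "Conv2d", "ConvTranspose2d", "LayerNorm",
    "BatchNorm2d", "MultiheadAttention", "Mlp", "AdamW", "cosine_lr",
]


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Container with recursive parameter discovery and state (de)serialization."""

    def named_parameters(self, prefix: str = ""):
        def walk(obj, path):
            if isinstance(obj, Parameter):
                yield path, obj
            elif isinstance(obj, Module):
                yield from obj.named_parameters(path + ".")
            elif isinstance(obj, (list, tuple)):
                for i, item in enumerate(obj):
                    yield from walk(item, f"{path}.{i}")

        for name, val in vars(self).items():
            if isinstance(val, (Parameter, Module, list, tuple)):
                yield from walk(val, f"{prefix}{name}")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def n_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def named_modules(self, prefix: str = ""):
        yield prefix, self

        def walk(obj, path):
            if isinstance(obj, Module):
                yield from obj.named_modules(path + ".")
            elif isinstance(obj, (list, tuple)):
                for i, item in enumerate(obj):
                    yield from walk(item, f"{path}.{i}")

        for name, val in vars(self).items():
            if isinstance(val, (Module, list, tuple)):
                yield from walk(val, f"{prefix}{name}")

    def named_buffers(self):
        """Non-trainable state (e.g. batch-norm running statistics)."""
        for path, mod in self.named_modules():
            for name in getattr(mod, "buffer_names", ()):
                yield f"{path}{name}", mod, name

    def state_dict(self) -> dict:
        out = {k: v.data.copy() for k, v in self.named_parameters()}
        for key, mod, name in self.named_buffers():
            out[key] = np.array(getattr(mod, name), copy=True)
        return out

    def load_state_dict(self, state: dict):
        own = dict(self.named_parameters())
        missing = set(own) - set(state)
        if missing:
            raise KeyError(f"missing parameters in state: {sorted(missing)}")
        for k, p in own.items():
            if p.data.shape != state[k].shape:
                raise ValueError(f"shape mismatch for {k}")
            p.data = np.asarray(state[k], dtype=np.float64).copy()
        for key, mod, name in self.named_buffers():
            if key in state:
                setattr(mod, name, np.array(state[key], copy=True))


def _trunc_normal(rng: np.random.Generator, shape, std: float) -> np.ndarray:
    x = rng.standard_normal(shape) * std
    return np.clip(x, -2 * std, 2 * std)


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator,
                 bias: bool = True, zero_init: bool = False):
        std = math.sqrt(2.0 / (d_in + d_out))
        w = np.zeros((d_in, d_out)) if zero_init else _trunc_normal(rng, (d_in, d_out), std)
        self.weight = Parameter(w)
        self.bias = Parameter(np.zeros(d_out)) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        y = x @ self.weight
        return y if self.bias is None else y + self.bias


class Conv2d(Module):
    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator,
                 stride: int = 1, pad: int = 0, bias: bool = True):
        fan_in = c_in * k * k
        self.weight = Parameter(_trunc_normal(rng, (c_out, c_in, k, k), math.sqrt(2.0 / fan_in)))
        self.bias = Parameter(np.zeros(c_out)) if bias else None
        self.stride, self.pad = stride, pad

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, self.stride, self.pad)


class ConvTranspose2d(Module):
    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator,
                 stride: int = 2, bias: bool = True):
        fan_in = c_in * k * k
        self.weight = Parameter(_trunc_normal(rng, (c_in, c_out, k, k), math.sqrt(2.0 / fan_in)))
        self.bias = Parameter(np.zeros(c_out)) if bias else None
        self.stride = stride

    def __call__(self, x: Tensor) -> Tensor:
        return conv_transpose2d(x, self.weight, self.bias, self.stride)


class LayerNorm(Module):
    """Normalizes the trailing axis (token channels)."""

    def __init__(self, dim: int, eps: float = 1e-6):
        self.gamma = Parameter(np.ones(dim))
        self.beta = Parameter(np.zeros(dim))
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        return xc * (var + self.eps) ** -0.5 * self.gamma + self.beta


class ChannelLayerNorm(LayerNorm):
    """LayerNorm over the channel axis of a (C,H,W) map."""

    def __call__(self, x: Tensor) -> Tensor:  # noqa: D102
        y = super().__call__(x.transpose(1, 2, 0))
        return y.transpose(2, 0, 1)


class BatchNorm2d(Module):
    """Per-channel normalization of a (C,H,W) map over its spatial extent.

    With batch size 1 the normalization statistics are the spatial statistics;
    running estimates are tracked for inference.
    """

    def __init__(self, c: int, eps: float = 1e-5, momentum: float = 0.1):
        self.gamma = Parameter(np.ones((c, 1, 1)))
        self.beta = Parameter(np.zeros((c, 1, 1)))
        self.eps, self.momentum = eps, momentum
        self.running_mean = np.zeros((c, 1, 1))
        self.running_var = np.ones((c, 1, 1))
        self.training = True

    buffer_names = ("running_mean", "running_var")

    def __call__(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.mean(axis=(1, 2), keepdims=True)
            xc = x - mu
            var = (xc * xc).mean(axis=(1, 2), keepdims=True)
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mu.data
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var.data
            return xc * (var + self.eps) ** -0.5 * self.gamma + self.beta
        xc = x - Tensor(self.running_mean)
        return xc * Tensor(1.0 / np.sqrt(self.running_var + self.eps)) * self.gamma + self.beta


class MultiheadAttention(Module):
    """Standard scaled dot-product attention on (N, C) token matrices.

    ``zero_init_out`` zeroes the output projection so the block is the
    identity at initialization when wrapped in a residual connection.
    """

    def __init__(self, dim: int, n_heads: int, rng: np.random.Generator,
                 kv_dim: int | None = None, zero_init_out: bool = False):
        if dim % n_heads:
            raise ValueError(f"n_heads={n_heads} must divide dim={dim}")
        kv_dim = kv_dim or dim
        self.n_heads, self.dh = n_heads, dim // n_heads
        self.q = Linear(dim, dim, rng)
        self.k = Linear(kv_dim, dim, rng)
        self.v = Linear(kv_dim, dim, rng)
        self.out = Linear(dim, dim, rng, zero_init=zero_init_out)

    def _split(self, t: Tensor, n: int) -> Tensor:
        return t.reshape(n, self.n_heads, self.dh).transpose(1, 0, 2)

    def __call__(self, q: Tensor, k: Tensor, v: Tensor) -> Tensor:
        nq, nk = q.shape[0], k.shape[0]
        qh = self._split(self.q(q), nq)
        kh = self._split(self.k(k), nk)
        vh = self._split(self.v(v), nk)
        att = (qh @ kh.transpose(0, 2, 1)) * (1.0 / math.sqrt(self.dh))
        att = att.softmax(axis=-1)
        out = (att @ vh).transpose(1, 0, 2).reshape(nq, self.n_heads * self.dh)
        return self.out(out)

    def attention_weights(self, q: Tensor, k: Tensor) -> np.ndarray:
        """Post-softmax attention map (heads, Nq, Nk); diagnostic only."""
        nq, nk = q.shape[0], k.shape[0]
        qh = self._split(self.q(q), nq)
        kh = self._split(self.k(k), nk)
        att = (qh @ kh.transpose(0, 2, 1)) * (1.0 / math.sqrt(self.dh))
        return att.softmax(axis=-1).data


class Mlp(Module):
    def __init__(self, dim: int, hidden: int, rng: np.random.Generator,
                 d_out: int | None = None):
        self.fc1 = Linear(dim, hidden, rng)
        self.fc2 = Linear(hidden, d_out or dim, rng)

    def __call__(self, x: Tensor) -> Tensor:
        return self.fc2(self.fc1(x).gelu())


class AdamW:
    """Decoupled weight-decay Adam."""

    def __init__(self, params, lr: float = 2e-4, betas=(0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 0.01):
        self.params = list(params)
        self.lr, self.betas, self.eps, self.wd = lr, betas, eps, weight_decay
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self):
        self.t += 1
        b1, b2 = self.betas
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1 ** self.t)
            vhat = self.v[i] / (1 - b2 ** self.t)
            p.data -= self.lr * (mhat / (np.sqrt(vhat) + self.eps) + self.wd * p.data)

    def zero_grad(self):
        for p in self.params:
            p.grad = None


def cosine_lr(step: int, total: int, lr_max: float, lr_min: float = 1e-6) -> float:
    """Cosine-annealed learning rate from ``lr_max`` (step 0) to ``lr_min``."""
    if total <= 1:
        return lr_max
    frac = min(step, total - 1) / (total - 1)
    return lr_min + 0.5 * (lr_max - lr_min) * (1 + math.cos(math.pi * frac))
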