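"""Minimal reverse-mode automatic differentiation over NumPy arrays.

A :class:`Tensor` wraps an ``ndarray`` and records the operations applied to
it; :meth:`Tensor.backward` runs reverse-mode accumulation through the
recorded graph.  The primitive set is exactly what the bronchoscopy model
needs — elementwise maps, reductions, (batched) matmul, 2-D convolution and
its transpose, shape surgery — nothing more.  Arrays are kept in float64 so
gradient checks against central differences are tight.
"""

from __future__ import annotations

import numpy as np
from scipy.special import erf

__all__ = ["Tensor", "as_tensor", "concat", "no_grad"]

_grad_enabled = True


class no_grad:
    """Context manager disabling graph recording (inference mode)."""

    def __enter__(self):
        global _grad_enabled
        self._prev = _grad_enabled
        _grad_enabled = False
        return self

    def __exit__(self, *exc):
        global _grad_enabled
        _grad_enabled = self._prev
        return False


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum leading extra axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple = ()
        self._backward = None

    # ------------------------------------------------------------------ infra
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

    def numpy(self) -> np.ndarray:
        return self.data

    def item(self) -> float:
        return float(self.data)

    def zero_grad(self):
        self.grad = None

    @staticmethod
    def _make(data, parents, backward):
        out = Tensor(data)
        if _grad_enabled and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar output")
            grad = np.ones_like(self.data)
        else:
            grad = np.asarray(grad, dtype=np.float64)
        # topological order
        topo, seen = [], set()
        stack = [(self, False)]
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
        grads = {id(self): grad}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node._backward is not None:
                for parent, pg in zip(node._parents, node._backward(g)):
                    if not parent.requires_grad or pg is None:
                        continue
                    if id(parent) in grads:
                        grads[id(parent)] = grads[id(parent)] + pg
                    else:
                        grads[id(parent)] = pg
            else:  # leaf
                node.grad = g if node.grad is None else node.grad + g

    # ------------------------------------------------------------ arithmetic
    def __add__(self, other):
        other = as_tensor(other)
        out_data = self.data + other.data
        sa, sb = self.data.shape, other.data.shape

        def backward(g):
            return _unbroadcast(g, sa), _unbroadcast(g, sb)

        return Tensor._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        return Tensor._make(-self.data, (self,), lambda g: (-g,))

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        a, b = self.data, other.data

        def backward(g):
            return _unbroadcast(g * b, a.shape), _unbroadcast(g * a, b.shape)

        return Tensor._make(a * b, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        return self * other ** -1.0

    def __rtruediv__(self, other):
        return as_tensor(other) * self ** -1.0

    def __pow__(self, p: float):
        a = self.data

        def backward(g):
            return (g * p * a ** (p - 1.0),)

        return Tensor._make(a ** p, (self,), backward)

    def __matmul__(self, other):
        other = as_tensor(other)
        a, b = self.data, other.data
        out = np.matmul(a, b)

        def backward(g):
            if b.ndim == 1:
                ga = np.multiply.outer(g, b) if a.ndim > 1 else g * b
                gb = np.matmul(np.swapaxes(a, -1, -2), g) if a.ndim > 1 else g * a
            elif a.ndim == 1:
                ga = np.matmul(g, np.swapaxes(b, -1, -2))
                gb = np.multiply.outer(a, g)
            else:
                ga = np.matmul(g, np.swapaxes(b, -1, -2))
                gb = np.matmul(np.swapaxes(a, -1, -2), g)
            return _unbroadcast(ga, a.shape), _unbroadcast(gb, b.shape)

        return Tensor._make(out, (self, other), backward)

    # ----------------------------------------------------------- elementwise
    def exp(self):
        e = np.exp(self.data)
        return Tensor._make(e, (self,), lambda g: (g * e,))

    def log(self):
        a = self.data
        return Tensor._make(np.log(a), (self,), lambda g: (g / a,))

    def sin(self):
        a = self.data
        return Tensor._make(np.sin(a), (self,), lambda g: (g * np.cos(a),))

    def cos(self):
        a = self.data
        return Tensor._make(np.cos(a), (self,), lambda g: (-g * np.sin(a),))

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-self.data))
        return Tensor._make(s, (self,), lambda g: (g * s * (1.0 - s),))

    def gelu(self):
        """Exact (erf-based) Gaussian error linear unit."""
        x = self.data
        phi = 0.5 * (1.0 + erf(x / np.sqrt(2.0)))
        out = x * phi

        def backward(g):
            pdf = np.exp(-0.5 * x * x) / np.sqrt(2.0 * np.pi)
            return (g * (phi + x * pdf),)

        return Tensor._make(out, (self,), backward)

    def relu(self):
        m = self.data > 0

        def backward(g):
            return (g * m,)

        return Tensor._make(self.data * m, (self,), backward)

    # ------------------------------------------------------------ reductions
    def sum(self, axis=None, keepdims=False):
        a_shape = self.data.shape
        out = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            return (np.broadcast_to(g, a_shape).copy(),)

        return Tensor._make(out, (self,), backward)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[ax] for ax in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    # ---------------------------------------------------------- shape surgery
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        a_shape = self.data.shape
        return Tensor._make(
            self.data.reshape(shape), (self,), lambda g: (g.reshape(a_shape),)
        )

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        return Tensor._make(
            self.data.transpose(axes), (self,), lambda g: (g.transpose(inv),)
        )

    def __getitem__(self, idx):
        a_shape = self.data.shape

        def backward(g):
            full = np.zeros(a_shape)
            np.add.at(full, idx, g)
            return (full,)

        return Tensor._make(self.data[idx], (self,), backward)

    def pad2d(self, pad: int):
        """Zero-pad the trailing two axes symmetrically by ``pad``."""
        if pad == 0:
            return self
        width = [(0, 0)] * (self.data.ndim - 2) + [(pad, pad), (pad, pad)]
        out = np.pad(self.data, width)
        sl = (Ellipsis, slice(pad, -pad), slice(pad, -pad))
        return Tensor._make(out, (self,), lambda g: (g[sl],))

    # -------------------------------------------------------------- softmax
    def softmax(self, axis=-1):
        shifted = self - self.data.max(axis=axis, keepdims=True)
        e = shifted.exp()
        return e / e.sum(axis=axis, keepdims=True)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concat(tensors, axis=0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor._make(out, tuple(tensors), backward)


# --------------------------------------------------------------- convolution
def _im2col(x: np.ndarray, k: int, stride: int, pad: int):
    """(C,H,W) -> (C*k*k, Ho*Wo) column matrix."""
    c, h, w = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (pad, pad), (pad, pad)))
    ho = (h + 2 * pad - k) // stride + 1
    wo = (w + 2 * pad - k) // stride + 1
    s0, s1, s2 = x.strides
    view = np.lib.stride_tricks.as_strided(
        x, (c, k, k, ho, wo), (s0, s1, s2, s1 * stride, s2 * stride)
    )
    return view.reshape(c * k * k, ho * wo), (ho, wo)


def _col2im(cols: np.ndarray, x_shape, k: int, stride: int, pad: int):
    """Adjoint of :func:`_im2col` (scatter-add)."""
    c, h, w = x_shape
    hp, wp = h + 2 * pad, w + 2 * pad
    ho = (hp - k) // stride + 1
    wo = (wp - k) // stride + 1
    x = np.zeros((c, hp, wp))
    cols = cols.reshape(c, k, k, ho, wo)
    for i in range(k):
        for j in range(k):
            x[:, i : i + stride * ho : stride, j : j + stride * wo : stride] += cols[:, i, j]
    if pad:
        x = x[:, pad:-pad, pad:-pad]
    return x


def conv2d(x: Tensor, w: Tensor, b: Tensor | None, stride: int = 1, pad: int = 0) -> Tensor:
    """2-D convolution (cross-correlation) of a (C,H,W) map with (Co,Ci,k,k) weights."""
    ci, h, wd = x.data.shape
    co, ci2, k, _ = w.data.shape
    if ci != ci2:
        raise ValueError(f"channel mismatch: input {ci}, weight {ci2}")
    cols, (ho, wo) = _im2col(x.data, k, stride, pad)
    wmat = w.data.reshape(co, ci * k * k)
    out = (wmat @ cols).reshape(co, ho, wo)
    if b is not None:
        out = out + b.data[:, None, None]

    def backward(g):
        gm = g.reshape(co, ho * wo)
        gw = (gm @ cols.T).reshape(w.data.shape)
        gx = _col2im(wmat.T @ gm, (ci, h, wd), k, stride, pad)
        gb = None if b is None else g.sum(axis=(1, 2))
        return (gx, gw) if b is None else (gx, gw, gb)

    parents = (x, w) if b is None else (x, w, b)
    return Tensor._make(out, parents, backward)


def conv_transpose2d(x: Tensor, w: Tensor, b: Tensor | None, stride: int = 2) -> Tensor:
    """Transposed convolution: (Ci,H,W) with (Ci,Co,k,k) weights -> (Co, s(H-1)+k, ...).

    Implemented as the adjoint of :func:`conv2d` (col2im of the weight-projected
    input), so with k == stride it performs exact non-overlapping upsampling.
    """
    ci, h, wd = x.data.shape
    ci2, co, k, _ = w.data.shape
    if ci != ci2:
        raise ValueError(f"channel mismatch: input {ci}, weight {ci2}")
    ho, wo = stride * (h - 1) + k, stride * (wd - 1) + k
    wmat = w.data.reshape(ci, co * k * k)  # maps Ci -> Co*k*k
    xin = x.data.reshape(ci, h * wd)
    cols = wmat.T @ xin  # (Co*k*k, H*W)
    out = _col2im(cols, (co, ho, wo), k, stride, 0)
    if b is not None:
        out = out + b.data[:, None, None]

    def backward(g):
        gcols, _ = _im2col(g, k, stride, 0)  # (Co*k*k, H*W)
        gx = (wmat @ gcols).reshape(ci, h, wd)
        gw = (xin @ gcols.T).reshape(ci, co * k * k).reshape(w.data.shape)
        gb = None if b is None else g.sum(axis=(1, 2))
        return (gx, gw) if b is None else (gx, gw, gb)

    parents = (x, w) if b is None else (x, w, b)
    return Tensor._make(out, parents, backward)


# ------------------------------------------------------------------ resizing
def _interp_matrix(n_in: int, n_out: int) -> np.ndarray:
    """Row-stochastic bilinear interpolation matrix (half-pixel centers)."""
    m = np.zeros((n_out, n_in))
    if n_in == 1:
        m[:, 0] = 1.0
        return m
    scale = n_in / n_out
    for i in range(n_out):
        src = (i + 0.5) * scale - 0.5
        src = min(max(src, 0.0), n_in - 1.0)
        lo = int(np.floor(src))
        hi = min(lo + 1, n_in - 1)
        t = src - lo
        m[i, lo] += 1.0 - t
        m[i, hi] += t
    return m


def resize_bilinear(x: Tensor, out_hw: tuple) -> Tensor:
    """Bilinear resize of a (C,H,W) tensor to (C, H2, W2); linear, so autodiff-exact."""
    _, h, w = x.data.shape
    h2, w2 = out_hw
    ry = Tensor(_interp_matrix(h, h2))
    rx = Tensor(_interp_matrix(w, w2).T)
    return (ry @ x) @ rx


def upsample_nearest(x: Tensor, factor: int) -> Tensor:
    """Nearest-neighbour upsampling of a (C,H,W) tensor by an integer factor."""
    c, h, w = x.data.shape
    out = np.repeat(np.repeat(x.data, factor, axis=1), factor, axis=2)

    def backward(g):
        g = g.reshape(c, h, factor, w, factor)
        return (g.sum(axis=(2, 4)),)

    return Tensor._make(out, (x,), backward)
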