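"""Minimal reverse-mode automatic differentiation over NumPy arrays.

The detector, its losses and the SGD trainer are all expressed in terms of
:class:`Tensor`, a thin wrapper around an ``ndarray`` that records enough of
the computation graph to backpropagate.  Only the operations the network
actually uses are implemented: elementwise arithmetic with broadcasting,
matmul, the activations (sigmoid / SiLU / Leaky ReLU), reductions, indexing,
concatenation, 2-D convolution via im2col, stride-1 same-padding max pooling,
nearest-neighbour 2x upsampling and a numerically stable binary cross-entropy
on logits.

Gradients accumulate into ``.grad`` (an ndarray of the same shape and dtype
as ``.data``).  Graph recording is skipped entirely when no input requires a
gradient, so inference costs no bookkeeping.
"""

from __future__ import annotations

import numpy as np


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (the reverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndim_extra = grad.ndim - len(shape)
    if ndim_extra > 0:
        grad = grad.sum(axis=tuple(range(ndim_extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """An ndarray plus the backward closure that produced it."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple = ()

    # -- graph plumbing ----------------------------------------------------

    @staticmethod
    def _result(data, parents, backward):
        needs = any(p.requires_grad for p in parents)
        out = Tensor(data, requires_grad=needs)
        if needs:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accum(self, grad):
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += grad

    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for t in reversed(topo):
            if t._backward is not None:
                t._backward(t.grad)

    def zero_graph(self):
        """Drop the recorded graph (keeps data); frees forward activations."""
        self._parents = ()
        self._backward = None

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    # -- conveniences ------------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(np.asarray(other))

    # -- elementwise arithmetic -------------------------------------------

    def __add__(self, other):
        other = self._wrap(other)
        a, b = self, other

        def backward(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g, a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g, b.data.shape))

        return self._result(a.data + b.data, (a, b), backward)

    __radd__ = __add__

    def __neg__(self):
        a = self

        def backward(g):
            a._accum(-g)

        return self._result(-a.data, (a,), backward)

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)
        a, b = self, other

        def backward(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g * b.data, a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g * a.data, b.data.shape))

        return self._result(a.data * b.data, (a, b), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._wrap(other)
        return self * other ** -1.0

    def __rtruediv__(self, other):
        return self._wrap(other) * self ** -1.0

    def __pow__(self, exponent: float):
        a = self
        out_data = a.data ** exponent

        def backward(g):
            a._accum(g * exponent * a.data ** (exponent - 1.0))

        return self._result(out_data, (a,), backward)

    def __matmul__(self, other):
        other = self._wrap(other)
        a, b = self, other
        if a.data.ndim != 2 or b.data.ndim != 2:
            raise ValueError("matmul supports 2-D operands only")

        def backward(g):
            if a.requires_grad:
                a._accum(g @ b.data.T)
            if b.requires_grad:
                b._accum(a.data.T @ g)

        return self._result(a.data @ b.data, (a, b), backward)

    # -- activations -------------------------------------------------------

    def sigmoid(self) -> "Tensor":
        a = self
        s = _sigmoid(a.data)

        def backward(g):
            a._accum(g * s * (1.0 - s))

        return self._result(s, (a,), backward)

    def silu(self) -> "Tensor":
        a = self
        s = _sigmoid(a.data)
        out = a.data * s

        def backward(g):
            a._accum(g * (s + out * (1.0 - s)))

        return self._result(out, (a,), backward)

    def leaky_relu(self, negative_slope: float = 0.1) -> "Tensor":
        a = self
        mask = a.data >= 0

        def backward(g):
            a._accum(g * np.where(mask, 1.0, negative_slope).astype(a.data.dtype))

        out = np.where(mask, a.data, a.data * negative_slope)
        return self._result(out, (a,), backward)

    def exp(self) -> "Tensor":
        a = self
        out = np.exp(a.data)

        def backward(g):
            a._accum(g * out)

        return self._result(out, (a,), backward)

    def log(self) -> "Tensor":
        a = self

        def backward(g):
            a._accum(g / a.data)

        return self._result(np.log(a.data), (a,), backward)

    def sqrt(self) -> "Tensor":
        return self ** 0.5

    def clamp_min(self, lo: float) -> "Tensor":
        a = self
        mask = a.data >= lo

        def backward(g):
            a._accum(g * mask)

        return self._result(np.where(mask, a.data, lo), (a,), backward)

    def minimum(self, other) -> "Tensor":
        other = self._wrap(other)
        a, b = self, other
        take_a = a.data <= b.data

        def backward(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g * take_a, a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g * ~take_a, b.data.shape))

        return self._result(np.minimum(a.data, b.data), (a, b), backward)

    def maximum(self, other) -> "Tensor":
        other = self._wrap(other)
        a, b = self, other
        take_a = a.data >= b.data

        def backward(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g * take_a, a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g * ~take_a, b.data.shape))

        return self._result(np.maximum(a.data, b.data), (a, b), backward)

    # -- reductions / shape ops -------------------------------------------

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        a = self
        out = a.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            if axis is None:
                grad = np.broadcast_to(g, a.data.shape)
            else:
                axes = (axis,) if isinstance(axis, int) else tuple(axis)
                if not keepdims:
                    g = np.expand_dims(g, axes)
                grad = np.broadcast_to(g, a.data.shape)
            a._accum(grad.astype(a.data.dtype, copy=False))

        return self._result(out, (a,), backward)

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[ax] for ax in ((axis,) if isinstance(axis, int) else axis)]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape) -> "Tensor":
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        a = self

        def backward(g):
            a._accum(g.reshape(a.data.shape))

        return self._result(a.data.reshape(shape), (a,), backward)

    def transpose(self, axes) -> "Tensor":
        a = self
        inv = np.argsort(axes)

        def backward(g):
            a._accum(g.transpose(inv))

        return self._result(a.data.transpose(axes), (a,), backward)

    def __getitem__(self, idx) -> "Tensor":
        a = self

        def backward(g):
            full = np.zeros_like(a.data)
            np.add.at(full, idx, g)
            a._accum(full)

        return self._result(a.data[idx], (a,), backward)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    # clipping at ±60 keeps exp() in range; sigmoid saturates there anyway
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60.0, 60.0)))


def concat(tensors, axis: int = 0) -> Tensor:
    tensors = [Tensor._wrap(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accum(g[tuple(sl)])

    return Tensor._result(np.concatenate([t.data for t in tensors], axis=axis),
                          tuple(tensors), backward)


# -- spatial ops (NCHW) ----------------------------------------------------

def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None,
           stride: int = 1, padding: int = 0) -> Tensor:
    """2-D convolution (cross-correlation), NCHW input, OIHW weights."""
    n, c, h, wdt = x.data.shape
    o, ci, kh, kw = w.data.shape
    if ci != c:
        raise ValueError(f"conv2d channel mismatch: input {c}, weight expects {ci}")
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    ho = (h + 2 * padding - kh) // stride + 1
    wo = (wdt + 2 * padding - kw) // stride + 1
    win = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
    win = win[:, :, ::stride, ::stride]                  # (n, c, ho, wo, kh, kw)
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * ho * wo, c * kh * kw)
    wmat = w.data.reshape(o, -1)
    out = cols @ wmat.T
    if b is not None:
        out += b.data
    out = out.reshape(n, ho, wo, o).transpose(0, 3, 1, 2)
    parents = (x, w) if b is None else (x, w, b)

    def backward(g):
        gmat = g.transpose(0, 2, 3, 1).reshape(n * ho * wo, o)
        if w.requires_grad:
            w._accum((gmat.T @ cols).reshape(w.data.shape))
        if b is not None and b.requires_grad:
            b._accum(gmat.sum(axis=0))
        if x.requires_grad:
            dcols = (gmat @ wmat).reshape(n, ho, wo, c, kh, kw)
            dxp = np.zeros_like(xp)
            for i in range(kh):
                for j in range(kw):
                    dxp[:, :, i:i + stride * ho:stride, j:j + stride * wo:stride] += \
                        dcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
            if padding:
                dxp = dxp[:, :, padding:-padding, padding:-padding]
            x._accum(dxp)

    return Tensor._result(out, parents, backward)


def maxpool2d_same(x: Tensor, kernel: int) -> Tensor:
    """Max pooling with stride 1 and same padding; `kernel` must be odd."""
    if kernel % 2 == 0:
        raise ValueError(f"max-pool kernel must be odd, got {kernel}")
    p = kernel // 2
    n, c, h, w = x.data.shape
    fill = -np.inf if np.issubdtype(x.data.dtype, np.floating) else np.iinfo(x.data.dtype).min
    xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p)), constant_values=fill)
    win = np.lib.stride_tricks.sliding_window_view(xp, (kernel, kernel), axis=(2, 3))
    flat = win.reshape(n, c, h, w, kernel * kernel)
    arg = flat.argmax(axis=-1)
    out = np.take_along_axis(flat, arg[..., None], axis=-1)[..., 0]

    def backward(g):
        gi, gj = np.divmod(arg, kernel)
        hh, ww = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
        rows = hh[None, None] + gi
        cols_ = ww[None, None] + gj
        nn_, cc = np.meshgrid(np.arange(n), np.arange(c), indexing="ij")
        gpad = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=g.dtype)
        np.add.at(gpad, (nn_[..., None, None], cc[..., None, None], rows, cols_), g)
        x._accum(gpad[:, :, p:-p, p:-p] if p else gpad)

    return Tensor._result(out, (x,), backward)


def upsample2x(x: Tensor) -> Tensor:
    """Nearest-neighbour 2x spatial upsampling."""
    a = x
    out = a.data.repeat(2, axis=2).repeat(2, axis=3)
    n, c, h, w = a.data.shape

    def backward(g):
        a._accum(g.reshape(n, c, h, 2, w, 2).sum(axis=(3, 5)))

    return Tensor._result(out, (a,), backward)


def bce_with_logits(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Elementwise binary cross-entropy on logits, numerically stable.

    `targets` is a plain ndarray in [0, 1] (no gradient flows to it).
    Returns a tensor of the same shape; reduce with .mean()/.sum().
    """
    t = np.asarray(targets, dtype=logits.data.dtype)
    z = logits.data
    loss = np.maximum(z, 0) - z * t + np.log1p(np.exp(-np.abs(z)))
    a = logits

    def backward(g):
        a._accum(g * (_sigmoid(z) - t))

    return Tensor._result(loss, (a,), backward)
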