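"""Minimal reverse-mode automatic differentiation over numpy arrays.

The segmentation network in this package is trained with plain numpy: a
:class:`Tensor` wraps an ndarray, records its parent tensors and a backward
closure, and :meth:`Tensor.backward` propagates gradients in reverse
topological order.  Only the operations the network needs are provided:
elementwise arithmetic with broadcasting, 2-D matrix multiplication,
same-size 2-D convolution (im2col), depthwise convolution, 2x2 average
pooling, 2x nearest-neighbour upsampling, concatenation/slicing along the
channel axis, reductions, and the relu/sigmoid nonlinearities.

Arrays are float32 throughout; image batches use NCHW layout
(batch, channels, height, width).  All operations are deterministic pure
functions of their inputs, so repeated forward passes with identical
parameters are bit-identical.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np

DTYPE = np.float32


class Tensor:
    """An ndarray node in a dynamically built computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "needs_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=DTYPE)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents = tuple(parents)
        self._backward = backward
        self.needs_grad = self.requires_grad or any(p.needs_grad for p in self._parents)

    # -- introspection -------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- autodiff ------------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        """Accumulate gradients of ``self`` w.r.t. every reachable parameter."""
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if p.needs_grad and id(p) not in seen:
                    stack.append((p, False))
        _accum(self, np.asarray(grad, dtype=DTYPE))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- operator sugar ------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __sub__(self, other):
        return sub(self, other)

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __neg__(self):
        return mul(self, -1.0)


def _wrap(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _accum(t: Tensor, g: np.ndarray) -> None:
    if not t.needs_grad:
        return
    t.grad = g if t.grad is None else t.grad + g


def _node(data, parents: Sequence[Tensor], backward) -> Tensor:
    # Constant-fold: when no parent can receive a gradient the node is a leaf
    # constant and the graph is not extended (keeps fixed branches cheap).
    if any(p.needs_grad for p in parents):
        return Tensor(data, parents=parents, backward=backward)
    return Tensor(data)


def _unbroadcast(g: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and g.shape[axis] != 1:
            g = g.sum(axis=axis, keepdims=True)
    return g


# ---------------------------------------------------------------------
# elementwise
# ---------------------------------------------------------------------

def add(a, b) -> Tensor:
    a, b = _wrap(a), _wrap(b)
    out = a.data + b.data

    def bwd(g):
        _accum(a, _unbroadcast(g, a.data.shape))
        _accum(b, _unbroadcast(g, b.data.shape))

    return _node(out, (a, b), bwd)


def sub(a, b) -> Tensor:
    a, b = _wrap(a), _wrap(b)
    out = a.data - b.data

    def bwd(g):
        _accum(a, _unbroadcast(g, a.data.shape))
        _accum(b, _unbroadcast(-g, b.data.shape))

    return _node(out, (a, b), bwd)


def mul(a, b) -> Tensor:
    a, b = _wrap(a), _wrap(b)
    out = a.data * b.data

    def bwd(g):
        _accum(a, _unbroadcast(g * b.data, a.data.shape))
        _accum(b, _unbroadcast(g * a.data, b.data.shape))

    return _node(out, (a, b), bwd)


def pow_scalar(a, exponent: float) -> Tensor:
    """Elementwise power with a constant exponent (base must stay positive
    on the differentiated path when ``exponent < 1``)."""
    a = _wrap(a)
    out = a.data ** exponent

    def bwd(g):
        _accum(a, g * exponent * a.data ** (exponent - 1.0))

    return _node(out, (a,), bwd)


def relu(a) -> Tensor:
    a = _wrap(a)
    mask = a.data > 0
    out = a.data * mask

    def bwd(g):
        _accum(a, g * mask)

    return _node(out, (a,), bwd)


def sigmoid(a) -> Tensor:
    a = _wrap(a)
    x = a.data
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)

    def bwd(g):
        _accum(a, g * out * (1.0 - out))

    return _node(out, (a,), bwd)


# ---------------------------------------------------------------------
# reductions and shape
# ---------------------------------------------------------------------

def _axes_tuple(axis, ndim) -> tuple[int, ...]:
    if axis is None:
        return tuple(range(ndim))
    if isinstance(axis, int):
        return (axis % ndim,)
    return tuple(ax % ndim for ax in axis)


def sum_(a, axis=None, keepdims: bool = False) -> Tensor:
    a = _wrap(a)
    axes = _axes_tuple(axis, a.data.ndim)
    out = a.data.sum(axis=axes, keepdims=keepdims)

    def bwd(g):
        shape = [1 if i in axes else s for i, s in enumerate(a.data.shape)]
        _accum(a, np.broadcast_to(g.reshape(shape), a.data.shape).astype(DTYPE))

    return _node(out, (a,), bwd)


def mean(a, axis=None, keepdims: bool = False) -> Tensor:
    a = _wrap(a)
    axes = _axes_tuple(axis, a.data.ndim)
    count = float(np.prod([a.data.shape[i] for i in axes]))
    out = a.data.mean(axis=axes, keepdims=keepdims)

    def bwd(g):
        shape = [1 if i in axes else s for i, s in enumerate(a.data.shape)]
        _accum(a, np.broadcast_to(g.reshape(shape) / count, a.data.shape).astype(DTYPE))

    return _node(out, (a,), bwd)


def reshape(a, shape) -> Tensor:
    a = _wrap(a)
    out = a.data.reshape(shape)

    def bwd(g):
        _accum(a, g.reshape(a.data.shape))

    return _node(out, (a,), bwd)


def concat(tensors: Iterable[Tensor], axis: int = 1) -> Tensor:
    ts = [_wrap(t) for t in tensors]
    out = np.concatenate([t.data for t in ts], axis=axis)
    sizes = [t.data.shape[axis] for t in ts]

    def bwd(g):
        start = 0
        for t, size in zip(ts, sizes):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(start, start + size)
            _accum(t, g[tuple(sl)])
            start += size

    return _node(out, tuple(ts), bwd)


def slice_channels(a, start: int, stop: int) -> Tensor:
    """Slice ``a[:, start:stop]`` along the channel axis of an NCHW tensor."""
    a = _wrap(a)
    out = a.data[:, start:stop]

    def bwd(g):
        ga = np.zeros_like(a.data)
        ga[:, start:stop] = g
        _accum(a, ga)

    return _node(out, (a,), bwd)


# ---------------------------------------------------------------------
# linear algebra
# ---------------------------------------------------------------------

def matmul(a, b) -> Tensor:
    """2-D matrix product ``(N, K) @ (K, M)``."""
    a, b = _wrap(a), _wrap(b)
    out = a.data @ b.data

    def bwd(g):
        _accum(a, g @ b.data.T)
        _accum(b, a.data.T @ g)

    return _node(out, (a, b), bwd)


# ---------------------------------------------------------------------
# convolution and resampling
# ---------------------------------------------------------------------

def _im2col(x: np.ndarray, kh: int, kw: int) -> np.ndarray:
    """(N, C, H, W) -> (N, C*kh*kw, H*W) with zero 'same' padding."""
    n, c, h, w = x.shape
    ph, pw = kh // 2, kw // 2
    xp = np.pad(x, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
    return np.ascontiguousarray(win.transpose(0, 1, 4, 5, 2, 3)).reshape(n, c * kh * kw, h * w)


def _col2im(gcols: np.ndarray, xshape: tuple[int, ...], kh: int, kw: int) -> np.ndarray:
    n, c, h, w = xshape
    ph, pw = kh // 2, kw // 2
    gx = np.zeros((n, c, h + 2 * ph, w + 2 * pw), dtype=DTYPE)
    g6 = gcols.reshape(n, c, kh, kw, h, w)
    for i in range(kh):
        for j in range(kw):
            gx[:, :, i:i + h, j:j + w] += g6[:, :, i, j]
    return gx[:, :, ph:ph + h, pw:pw + w]


def conv2d(x, weight, bias=None) -> Tensor:
    """Same-size cross-correlation of NCHW ``x`` with ``weight`` (O, C, kh, kw)."""
    x, weight = _wrap(x), _wrap(weight)
    n, c, h, w = x.data.shape
    o, cw, kh, kw = weight.data.shape
    if c != cw:
        raise ValueError(f"conv2d channel mismatch: input {c}, weight {cw}")
    cols = _im2col(x.data, kh, kw)
    w2 = weight.data.reshape(o, -1)
    out = np.matmul(w2, cols).reshape(n, o, h, w)
    if bias is not None:
        bias = _wrap(bias)
        out = out + bias.data.reshape(1, o, 1, 1)

    def bwd(g):
        g2 = g.reshape(n, o, -1)
        if weight.needs_grad:
            cols_b = _im2col(x.data, kh, kw)
            gw = np.matmul(g2, cols_b.transpose(0, 2, 1)).sum(axis=0)
            _accum(weight, gw.reshape(weight.data.shape))
        if bias is not None and bias.needs_grad:
            _accum(bias, g.sum(axis=(0, 2, 3)))
        if x.needs_grad:
            gcols = np.matmul(w2.T, g2)
            _accum(x, _col2im(gcols, x.data.shape, kh, kw))

    parents = (x, weight) if bias is None else (x, weight, bias)
    return _node(out, parents, bwd)


def depthwise_conv2d(x, weight, bias=None) -> Tensor:
    """Per-channel same-size convolution; ``weight`` has shape (C, kh, kw)."""
    x, weight = _wrap(x), _wrap(weight)
    n, c, h, w = x.data.shape
    cw, kh, kw = weight.data.shape
    if c != cw:
        raise ValueError(f"depthwise channel mismatch: input {c}, weight {cw}")
    ph, pw = kh // 2, kw // 2
    xp = np.pad(x.data, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
    out = np.einsum("nchwij,cij->nchw", win, weight.data, optimize=True)
    if bias is not None:
        bias = _wrap(bias)
        out = out + bias.data.reshape(1, c, 1, 1)

    def bwd(g):
        if weight.needs_grad:
            gw = np.einsum("nchwij,nchw->cij", win, g, optimize=True)
            _accum(weight, gw)
        if bias is not None and bias.needs_grad:
            _accum(bias, g.sum(axis=(0, 2, 3)))
        if x.needs_grad:
            gxp = np.zeros_like(xp)
            for i in range(kh):
                for j in range(kw):
                    gxp[:, :, i:i + h, j:j + w] += g * weight.data[:, i, j][None, :, None, None]
            _accum(x, gxp[:, :, ph:ph + h, pw:pw + w])

    parents = (x, weight) if bias is None else (x, weight, bias)
    return _node(out, parents, bwd)


def avg_pool2(x) -> Tensor:
    """2x2 average pooling with stride 2 (spatial sides must be even)."""
    x = _wrap(x)
    n, c, h, w = x.data.shape
    if h % 2 or w % 2:
        raise ValueError(f"avg_pool2 needs even spatial sides, got {h}x{w}")
    out = x.data.reshape(n, c, h // 2, 2, w // 2, 2).mean(axis=(3, 5))

    def bwd(g):
        _accum(x, np.repeat(np.repeat(g, 2, axis=2), 2, axis=3) * np.float32(0.25))

    return _node(out, (x,), bwd)


def upsample2(x) -> Tensor:
    """2x nearest-neighbour upsampling."""
    x = _wrap(x)
    n, c, h, w = x.data.shape
    out = np.repeat(np.repeat(x.data, 2, axis=2), 2, axis=3)

    def bwd(g):
        _accum(x, g.reshape(n, c, h, 2, w, 2).sum(axis=(3, 5)))

    return _node(out, (x,), bwd)


def mse(pred, target) -> Tensor:
    """Mean squared error against a constant target array."""
    pred = _wrap(pred)
    t = np.asarray(target, dtype=DTYPE)
    if t.shape != pred.data.shape:
        raise ValueError(f"mse shape mismatch: {pred.data.shape} vs {t.shape}")
    diff = pred.data - t
    out = np.asarray((diff * diff).mean(), dtype=DTYPE)

    def bwd(g):
        _accum(pred, g * diff * np.float32(2.0 / diff.size))

    return _node(out, (pred,), bwd)
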