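"""Minimal reverse-mode automatic differentiation on NumPy arrays.

Implements exactly the operator set the segmentation networks need:
broadcasting arithmetic, matmul, exp/log/pow, axis reductions, reshape /
transpose / slicing / concatenation, ReLU family, N-dimensional convolution
(2 or 3 spatial dims), factor-2 max-pooling and nearest-neighbour
up-sampling.  Gradients are accumulated by topological traversal of the
recorded graph; every custom operator is verified against central
differences in the test suite.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["Tensor", "concat", "softmax", "convnd", "maxpool2", "upsample2"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """An ndarray with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        arr = np.asarray(data)
        if arr.dtype.kind in "iub":
            arr = arr.astype(np.float64)
        self.data = arr
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple = ()
        self._backward = None

    # -- graph plumbing ----------------------------------------------------
    @staticmethod
    def _make(data, parents, backward):
        out = Tensor(data)
        out._parents = tuple(p for p in parents if isinstance(p, Tensor))
        out.requires_grad = any(p.requires_grad for p in out._parents)
        if out.requires_grad:
            out._backward = backward
        return out

    def _accumulate(self, g):
        if self.grad is None:
            self.grad = np.zeros(self.data.shape, dtype=self.data.dtype)
        self.grad += g

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
        self._accumulate(np.asarray(grad, dtype=self.data.dtype))
        for t in reversed(topo):
            if t._backward is not None:
                t._backward(t.grad)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self):
        self.grad = None

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def _coerce(self, other) -> "Tensor":
        """Wrap `other`; scalars adopt this tensor's dtype (so float32
        graphs stay float32 under NEP-50 promotion)."""
        if isinstance(other, Tensor):
            return other
        if np.isscalar(other):
            return Tensor(np.asarray(other, dtype=self.data.dtype))
        return Tensor(other)

    # -- arithmetic --------------------------------------------------------
    def __add__(self, other):
        o = self._coerce(other)
        out_data = self.data + o.data

        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.data.shape))
            if o.requires_grad:
                o._accumulate(_unbroadcast(g, o.data.shape))

        return Tensor._make(out_data, (self, o), bw)

    __radd__ = __add__

    def __neg__(self):
        def bw(g):
            if self.requires_grad:
                self._accumulate(-g)

        return Tensor._make(-self.data, (self,), bw)

    def __sub__(self, other):
        return self + (-self._coerce(other))

    def __rsub__(self, other):
        return Tensor(other) + (-self)

    def __mul__(self, other):
        o = self._coerce(other)
        out_data = self.data * o.data

        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * o.data, self.data.shape))
            if o.requires_grad:
                o._accumulate(_unbroadcast(g * self.data, o.data.shape))

        return Tensor._make(out_data, (self, o), bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        return self * self._coerce(other) ** -1.0

    def __rtruediv__(self, other):
        return Tensor(other) * self ** -1.0

    def __pow__(self, p: float):
        out_data = self.data ** p

        def bw(g):
            if self.requires_grad:
                self._accumulate(g * p * self.data ** (p - 1.0))

        return Tensor._make(out_data, (self,), bw)

    def __matmul__(self, other):
        o = self._coerce(other)
        out_data = self.data @ o.data

        def bw(g):
            if self.requires_grad:
                self._accumulate(g @ o.data.swapaxes(-1, -2))
            if o.requires_grad:
                o._accumulate(self.data.swapaxes(-1, -2) @ g)

        return Tensor._make(out_data, (self, o), bw)

    # -- elementwise functions ---------------------------------------------
    def exp(self):
        out_data = np.exp(self.data)

        def bw(g):
            if self.requires_grad:
                self._accumulate(g * out_data)

        return Tensor._make(out_data, (self,), bw)

    def log(self):
        def bw(g):
            if self.requires_grad:
                self._accumulate(g / self.data)

        return Tensor._make(np.log(self.data), (self,), bw)

    def clamp_min(self, lo: float):
        mask = self.data > lo

        def bw(g):
            if self.requires_grad:
                self._accumulate(g * mask)

        return Tensor._make(np.maximum(self.data, lo), (self,), bw)

    def relu(self):
        mask = self.data > 0

        def bw(g):
            if self.requires_grad:
                self._accumulate(g * mask)

        return Tensor._make(self.data * mask, (self,), bw)

    def leaky_relu(self, alpha: float = 0.01):
        one = self.data.dtype.type(1.0)
        factor = np.where(self.data > 0, one, self.data.dtype.type(alpha))

        def bw(g):
            if self.requires_grad:
                self._accumulate(g * factor)

        return Tensor._make(self.data * factor, (self,), bw)

    # -- reductions ----------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)
        axes = axis if axis is not None else tuple(range(self.data.ndim))
        if isinstance(axes, int):
            axes = (axes,)
        axes = tuple(a % self.data.ndim for a in axes)

        def bw(g):
            if not self.requires_grad:
                return
            if not keepdims:
                g = np.expand_dims(g, axes)
            self._accumulate(np.broadcast_to(g, self.data.shape).copy())

        return Tensor._make(out_data, (self,), bw)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = (axis,) if isinstance(axis, int) else axis
            n = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def max(self, axis: int, keepdims: bool = False):
        out_data = self.data.max(axis=axis, keepdims=keepdims)
        idx = self.data.argmax(axis=axis)

        def bw(g):
            if not self.requires_grad:
                return
            grad = np.zeros_like(self.data)
            gg = g if keepdims else np.expand_dims(g, axis)
            np.put_along_axis(grad, np.expand_dims(idx, axis), gg, axis=axis)
            self._accumulate(grad)

        return Tensor._make(out_data, (self,), bw)

    # -- shape ops -----------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.data.shape

        def bw(g):
            if self.requires_grad:
                self._accumulate(g.reshape(old))

        return Tensor._make(self.data.reshape(shape), (self,), bw)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)

        def bw(g):
            if self.requires_grad:
                self._accumulate(g.transpose(inv))

        return Tensor._make(self.data.transpose(axes), (self,), bw)

    def __getitem__(self, key):
        def bw(g):
            if self.requires_grad:
                grad = np.zeros_like(self.data)
                grad[key] += g
                self._accumulate(grad)

        return Tensor._make(self.data[key], (self,), bw)


def concat(tensors, axis: int = 0) -> Tensor:
    tensors = [t if isinstance(t, Tensor) else Tensor(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)

    def bw(g):
        start = 0
        for t, s in zip(tensors, sizes):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(start, start + s)
                t._accumulate(g[tuple(sl)])
            start += s

    return Tensor._make(out_data, tuple(tensors), bw)


def softmax(x: Tensor, axis: int = 1) -> Tensor:
    shift = Tensor(x.data.max(axis=axis, keepdims=True))  # constant, for stability
    e = (x - shift).exp()
    return e / e.sum(axis=axis, keepdims=True)


# -- spatial operators ------------------------------------------------------

def convnd(x: Tensor, w: Tensor, b: Tensor | None = None,
           stride: int = 1, padding: int | None = None) -> Tensor:
    """N-dim convolution (cross-correlation), x: (N,C,*S), w: (F,C,*k)."""
    x = x if isinstance(x, Tensor) else Tensor(x)
    nd = x.data.ndim - 2
    k = w.data.shape[2:]
    if padding is None:
        padding = k[0] // 2
    pads = [(0, 0), (0, 0)] + [(padding, padding)] * nd
    xp = np.pad(x.data, pads)
    win = sliding_window_view(xp, k, axis=tuple(range(2, 2 + nd)))
    if stride > 1:
        sl = (slice(None), slice(None)) + (slice(None, None, stride),) * nd
        win = win[sl]
    spec_f = "ncxyzijk,fcijk->nfxyz" if nd == 3 else "ncxyij,fcij->nfxy"
    out = np.einsum(spec_f, win, w.data, optimize=True)
    if b is not None:
        out = out + b.data.reshape((1, -1) + (1,) * nd)

    out_spatial = out.shape[2:]

    red_axes = (0,) + tuple(range(2, 2 + nd))  # batch + spatial

    def bw(g):
        g = np.ascontiguousarray(g, dtype=xp.dtype)
        need_dw = w.requires_grad
        need_dx = x.requires_grad
        dw = np.empty_like(w.data) if need_dw else None
        dxp = np.zeros_like(xp) if need_dx else None
        for offset in np.ndindex(*k):
            sl = (slice(None), slice(None)) + tuple(
                slice(o, o + s * stride, stride)
                for o, s in zip(offset, out_spatial))
            if need_dw:
                # dW[f,c,offset] = Σ_{n,pos} g[n,f,pos]·xp[n,c,pos+offset]
                dw[(slice(None), slice(None)) + offset] = np.tensordot(
                    g, xp[sl], axes=(red_axes, red_axes))
            if need_dx:
                ws = w.data[(slice(None), slice(None)) + offset]  # (F, C)
                contrib = np.tensordot(g, ws, axes=([1], [0]))  # (N,*So,C)
                dxp[sl] += np.moveaxis(contrib, -1, 1)
        if need_dw:
            w._accumulate(dw)
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=red_axes))
        if need_dx:
            un = (slice(None), slice(None)) + tuple(
                slice(padding, xp.shape[2 + i] - padding) for i in range(nd))
            x._accumulate(dxp[un])

    parents = (x, w) if b is None else (x, w, b)
    return Tensor._make(out, parents, bw)


def maxpool2(x: Tensor) -> Tensor:
    """Factor-2 max pooling over all spatial axes; dims must be even."""
    nd = x.data.ndim - 2
    n, c = x.data.shape[:2]
    spatial = x.data.shape[2:]
    if any(s % 2 for s in spatial):
        raise ValueError(f"maxpool2 needs even spatial dims, got {spatial}")
    half = tuple(s // 2 for s in spatial)
    shape = (n, c) + sum(((h, 2) for h in half), ())
    r = x.data.reshape(shape)
    # bring the 2-sized axes last: (n, c, *half, 2**nd)
    perm = (0, 1) + tuple(2 + 2 * i for i in range(nd)) + tuple(3 + 2 * i for i in range(nd))
    r = r.transpose(perm).reshape((n, c) + half + (2 ** nd,))
    out = r.max(axis=-1)
    idx = r.argmax(axis=-1)

    def bw(g):
        if not x.requires_grad:
            return
        dr = np.zeros_like(r)
        np.put_along_axis(dr, idx[..., None], g[..., None], axis=-1)
        dr = dr.reshape((n, c) + half + (2,) * nd).transpose(np.argsort(perm))
        x._accumulate(dr.reshape(x.data.shape))

    return Tensor._make(out, (x,), bw)


def upsample2(x: Tensor) -> Tensor:
    """Nearest-neighbour factor-2 up-sampling over all spatial axes."""
    nd = x.data.ndim - 2
    out = x.data
    for ax in range(2, 2 + nd):
        out = np.repeat(out, 2, axis=ax)

    def bw(g):
        if not x.requires_grad:
            return
        n, c = g.shape[:2]
        shape = (n, c) + sum(((s, 2) for s in x.data.shape[2:]), ())
        axes = tuple(3 + 2 * i for i in range(nd))
        x._accumulate(g.reshape(shape).sum(axis=axes))

    return Tensor._make(out, (x,), bw)
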