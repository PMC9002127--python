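"""Minimal reverse-mode automatic differentiation on numpy arrays.

The detector is small enough to train on a CPU, so instead of a deep
learning framework the package carries its own vectorized autodiff
engine: a :class:`Tensor` wraps an ``ndarray``, records the operation
that produced it, and ``backward()`` walks the graph in reverse
topological order accumulating gradients.  Broadcasting follows numpy
semantics (gradients are summed back over broadcast axes).

Only the operations the network and losses need are implemented:
elementwise arithmetic, exp/log/sqrt/tanh/sigmoid/relu/softplus, matmul,
reductions, reshape/transpose/concat/slicing, a stable softmax, strided
2-D convolution via im2col, fixed bilinear x2 upsampling, and a
scatter-add cell gather used to read head maps at ground-truth centers.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np

__all__ = ["Tensor", "concat", "softmax", "conv2d", "upsample2x", "gather_cells"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` back down to ``shape`` after numpy broadcasting."""
    if grad.shape == shape:
        return grad
    # sum away leading axes added by broadcasting
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # sum over axes that were 1 in the original shape
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    # make numpy defer to the reflected operators instead of broadcasting
    __array_ufunc__ = None
    __array_priority__ = 1000

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        arr = np.asarray(data)
        if arr.dtype not in (np.float32, np.float64):
            arr = arr.astype(np.float32)
        self.data = arr
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = parents
        self._backward = backward

    # -- graph -----------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def _accum(self, grad: np.ndarray) -> None:
        if self.grad is None:
            # copy: backward closures may hand the same buffer to two parents
            if grad.dtype == self.data.dtype:
                self.grad = grad.copy()
            else:
                self.grad = grad.astype(self.data.dtype)
        else:
            self.grad += grad

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self._accum(np.asarray(grad, dtype=self.data.dtype))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- elementwise arithmetic -----------------------------------------
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float32))

    def _lift_like(self, x) -> "Tensor":
        """Wrap a constant, matching this tensor's dtype (no silent promotion)."""
        if isinstance(x, Tensor):
            return x
        arr = np.asarray(x)
        if arr.dtype != self.data.dtype:
            arr = arr.astype(self.data.dtype)
        return Tensor(arr)

    def __add__(self, other):
        o = self._lift_like(other)
        out = Tensor(self.data + o.data, parents=(self, o))

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if o.requires_grad:
                o._accum(_unbroadcast(g, o.data.shape))

        out._backward = bwd
        return out

    __radd__ = __add__

    def __mul__(self, other):
        o = self._lift_like(other)
        out = Tensor(self.data * o.data, parents=(self, o))

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * o.data, self.data.shape))
            if o.requires_grad:
                o._accum(_unbroadcast(g * self.data, o.data.shape))

        out._backward = bwd
        return out

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-self._lift_like(other))

    def __rsub__(self, other):
        return self._lift_like(other) + (-self)

    def __truediv__(self, other):
        o = self._lift_like(other)
        out = Tensor(self.data / o.data, parents=(self, o))

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g / o.data, self.data.shape))
            if o.requires_grad:
                o._accum(_unbroadcast(-g * self.data / (o.data**2), o.data.shape))

        out._backward = bwd
        return out

    def __rtruediv__(self, other):
        return self._lift_like(other) / self

    def __pow__(self, exponent: float):
        out = Tensor(self.data**exponent, parents=(self,))

        def bwd(g):
            if self.requires_grad:
                self._accum(g * exponent * self.data ** (exponent - 1))

        out._backward = bwd
        return out

    def __matmul__(self, other):
        o = self._lift_like(other)
        out = Tensor(self.data @ o.data, parents=(self, o))

        def bwd(g):
            if self.requires_grad:
                ga = g @ np.swapaxes(o.data, -1, -2)
                self._accum(_unbroadcast(ga, self.data.shape))
            if o.requires_grad:
                gb = np.swapaxes(self.data, -1, -2) @ g
                o._accum(_unbroadcast(gb, o.data.shape))

        out._backward = bwd
        return out

    # -- unary nonlinearities -------------------------------------------
    def exp(self):
        y = np.exp(self.data)
        out = Tensor(y, parents=(self,))
        out._backward = lambda g: self.requires_grad and self._accum(g * y)
        return out

    def log(self):
        out = Tensor(np.log(self.data), parents=(self,))
        out._backward = lambda g: self.requires_grad and self._accum(g / self.data)
        return out

    def sqrt(self):
        y = np.sqrt(self.data)
        out = Tensor(y, parents=(self,))
        out._backward = lambda g: self.requires_grad and self._accum(g * 0.5 / y)
        return out

    def sin(self):
        out = Tensor(np.sin(self.data), parents=(self,))
        out._backward = lambda g: self.requires_grad and self._accum(g * np.cos(self.data))
        return out

    def cos(self):
        out = Tensor(np.cos(self.data), parents=(self,))
        out._backward = lambda g: self.requires_grad and self._accum(g * -np.sin(self.data))
        return out

    def tanh(self):
        y = np.tanh(self.data)
        out = Tensor(y, parents=(self,))
        out._backward = lambda g: self.requires_grad and self._accum(g * (1 - y * y))
        return out

    def sigmoid(self):
        y = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(y, parents=(self,))
        out._backward = lambda g: self.requires_grad and self._accum(g * y * (1 - y))
        return out

    def relu(self):
        mask = self.data > 0
        out = Tensor(np.where(mask, self.data, 0), parents=(self,))
        out._backward = lambda g: self.requires_grad and self._accum(g * mask)
        return out

    def softplus(self):
        # stable: log(1 + exp(x)) = max(x, 0) + log1p(exp(-|x|))
        y = np.maximum(self.data, 0) + np.log1p(np.exp(-np.abs(self.data)))
        sig = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(y, parents=(self,))
        out._backward = lambda g: self.requires_grad and self._accum(g * sig)
        return out

    def abs(self):
        sign = np.sign(self.data)
        out = Tensor(np.abs(self.data), parents=(self,))
        out._backward = lambda g: self.requires_grad and self._accum(g * sign)
        return out

    def clip(self, lo: float, hi: float):
        """Clamp values; gradient is passed only where unclipped."""
        mask = (self.data > lo) & (self.data < hi)
        out = Tensor(np.clip(self.data, lo, hi), parents=(self,))
        out._backward = lambda g: self.requires_grad and self._accum(g * mask)
        return out

    # -- reductions / shaping -------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), parents=(self,))

        def bwd(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape).copy())
                return
            gg = g
            if not keepdims:
                gg = np.expand_dims(gg, axis)
            self._accum(np.broadcast_to(gg, self.data.shape).copy())

        out._backward = bwd
        return out

    def mean(self, axis=None, keepdims=False):
        if axis is None:
            n = self.data.size
        elif isinstance(axis, tuple):
            n = int(np.prod([self.data.shape[a] for a in axis]))
        else:
            n = self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), parents=(self,))
        out._backward = lambda g: self.requires_grad and self._accum(g.reshape(self.data.shape))
        return out

    def transpose(self, *axes):
        inv = np.argsort(axes)
        out = Tensor(self.data.transpose(*axes), parents=(self,))
        out._backward = lambda g: self.requires_grad and self._accum(g.transpose(*inv))
        return out

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], parents=(self,))

        def bwd(g):
            if not self.requires_grad:
                return
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            self._accum(full)

        out._backward = bwd
        return out

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={'yes' if self.requires_grad else 'no'})"


def concat(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), parents=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bwd(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            if t.requires_grad:
                t._accum(piece)

    out._backward = bwd
    return out


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    z = x.data - x.data.max(axis=axis, keepdims=True)
    ez = np.exp(z)
    y = ez / ez.sum(axis=axis, keepdims=True)
    out = Tensor(y, parents=(x,))

    def bwd(g):
        if x.requires_grad:
            dot = (g * y).sum(axis=axis, keepdims=True)
            x._accum(y * (g - dot))

    out._backward = bwd
    return out


# -- convolution ---------------------------------------------------------


def _im2col(x: np.ndarray, kh: int, kw: int, stride: int, pad: int):
    n, c, h, w = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    ho = (h + 2 * pad - kh) // stride + 1
    wo = (w + 2 * pad - kw) // stride + 1
    cols = np.empty((n, c, kh, kw, ho, wo), dtype=x.dtype)
    for i in range(kh):
        for j in range(kw):
            cols[:, :, i, j] = x[:, :, i : i + stride * ho : stride, j : j + stride * wo : stride]
    return cols.reshape(n, c * kh * kw, ho * wo), ho, wo


def _col2im(cols: np.ndarray, x_shape, kh: int, kw: int, stride: int, pad: int) -> np.ndarray:
    n, c, h, w = x_shape
    ho = (h + 2 * pad - kh) // stride + 1
    wo = (w + 2 * pad - kw) // stride + 1
    cols = cols.reshape(n, c, kh, kw, ho, wo)
    xp = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=cols.dtype)
    for i in range(kh):
        for j in range(kw):
            xp[:, :, i : i + stride * ho : stride, j : j + stride * wo : stride] += cols[:, :, i, j]
    return xp[:, :, pad : pad + h, pad : pad + w] if pad else xp


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None, stride: int = 1, pad: int = 0) -> Tensor:
    """2-D convolution (cross-correlation), NCHW layout, via im2col."""
    oc, ic, kh, kw = weight.data.shape
    cols, ho, wo = _im2col(x.data, kh, kw, stride, pad)
    wmat = weight.data.reshape(oc, ic * kh * kw)
    y = np.einsum("ok,nkl->nol", wmat, cols, optimize=True)
    if bias is not None:
        y = y + bias.data[None, :, None]
    n = x.data.shape[0]
    parents = (x, weight) + ((bias,) if bias is not None else ())
    out = Tensor(y.reshape(n, oc, ho, wo), parents=parents)

    def bwd(g):
        gmat = g.reshape(n, oc, ho * wo)
        if weight.requires_grad:
            gw = np.einsum("nol,nkl->ok", gmat, cols, optimize=True)
            weight._accum(gw.reshape(weight.data.shape))
        if bias is not None and bias.requires_grad:
            bias._accum(gmat.sum(axis=(0, 2)))
        if x.requires_grad:
            gcols = np.einsum("ok,nol->nkl", wmat, gmat, optimize=True)
            x._accum(_col2im(gcols, x.data.shape, kh, kw, stride, pad))

    out._backward = bwd
    return out


# -- bilinear x2 upsampling ---------------------------------------------

_UP_CACHE: dict[int, np.ndarray] = {}


def _upsample_matrix(n: int) -> np.ndarray:
    """(2n x n) bilinear interpolation matrix (align_corners=False, edges clamped)."""
    if n in _UP_CACHE:
        return _UP_CACHE[n]
    m = np.zeros((2 * n, n), dtype=np.float32)
    for i in range(2 * n):
        c = (i + 0.5) / 2.0 - 0.5
        f = math.floor(c)
        t = c - f
        i0 = min(max(f, 0), n - 1)
        i1 = min(max(f + 1, 0), n - 1)
        m[i, i0] += 1.0 - t
        m[i, i1] += t
    _UP_CACHE[n] = m
    return m


def upsample2x(x: Tensor) -> Tensor:
    """Bilinear x2 spatial upsampling of an NCHW tensor."""
    n, c, h, w = x.data.shape
    mr = _upsample_matrix(h)
    mc = _upsample_matrix(w)
    y = np.einsum("ph,nchw,qw->ncpq", mr, x.data, mc, optimize=True)
    out = Tensor(y, parents=(x,))

    def bwd(g):
        if x.requires_grad:
            x._accum(np.einsum("ph,ncpq,qw->nchw", mr, g, mc, optimize=True))

    out._backward = bwd
    return out


def gather_cells(x: Tensor, batch_idx: np.ndarray, y_idx: np.ndarray, x_idx: np.ndarray) -> Tensor:
    """Read an NCHW map at per-object cells -> (K, C); gradient scatter-adds."""
    bi = np.asarray(batch_idx)
    yi = np.asarray(y_idx)
    xi = np.asarray(x_idx)
    out = Tensor(x.data[bi, :, yi, xi], parents=(x,))

    def bwd(g):
        if x.requires_grad:
            full = np.zeros_like(x.data)
            np.add.at(full, (bi, slice(None), yi, xi), g)
            x._accum(full)

    out._backward = bwd
    return out
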