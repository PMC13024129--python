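"""Reverse-mode automatic differentiation on numpy arrays.

A small define-by-run tape: every operation returns a new :class:`Tensor`
holding its value and a closure that routes the upstream gradient to its
inputs.  ``Tensor.backward()`` topologically sorts the tape and runs the
closures once.  Arrays are kept in float64 throughout; the networks in this
package are small enough that double precision on CPU is the simplest way to
make the analytic oracles (closed-form scans, finite differences) agree to
tight tolerances.

Only the operations the radar-BP networks need are implemented: broadcasted
arithmetic, the usual activations, matmul, reductions, slicing/reshaping,
1-D (transposed) convolution via im2col, linear 2x upsampling and
concatenation/stacking.  Convolution padding is handled internally; all
shapes follow the (batch, channels, length) convention used by 1-D signal
networks.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.special import erf

__all__ = ["Tensor", "concat", "stack", "conv1d", "conv_transpose1d", "upsample_linear2"]

_SQRT2 = math.sqrt(2.0)
_INV_SQRT2PI = 1.0 / math.sqrt(2.0 * math.pi)


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum away leading axes
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # sum axes that were broadcast from size 1
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False, _prev: tuple = ()):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad)
        self.grad: np.ndarray | None = None
        self._backward = None
        self._prev = _prev

    # -- bookkeeping ------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __len__(self):
        return len(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(g, dtype=np.float64, copy=True)
        else:
            self.grad += g

    def _accum_at(self, key, g: np.ndarray) -> None:
        """Accumulate into a basic-indexed slice (non-overlapping)."""
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad[key] += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [self]
        while stack:  # iterative DFS; graphs can be a few thousand nodes deep
            node = stack[-1]
            if id(node) in seen:
                stack.pop()
                continue
            unvisited = [p for p in node._prev if id(p) not in seen]
            if unvisited:
                stack.extend(unvisited)
            else:
                seen.add(id(node))
                topo.append(node)
                stack.pop()
        self.grad = np.ones_like(self.data) if grad is None else np.asarray(grad, dtype=np.float64)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
        # free intermediate grads/graph? keep; caller controls lifetime

    # -- arithmetic -------------------------------------------------------
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = Tensor._lift(other)
        out = Tensor(self.data + other.data,
                     self.requires_grad or other.requires_grad, (self, other))
        if out.requires_grad:
            def _bw(g):
                if self.requires_grad or self._prev:
                    self._accum(_unbroadcast(g, self.data.shape))
                if other.requires_grad or other._prev:
                    other._accum(_unbroadcast(g, other.data.shape))
            out._backward = _bw
        return out

    __radd__ = __add__

    def __mul__(self, other):
        other = Tensor._lift(other)
        out = Tensor(self.data * other.data,
                     self.requires_grad or other.requires_grad, (self, other))
        if out.requires_grad:
            def _bw(g):
                if self.requires_grad or self._prev:
                    self._accum(_unbroadcast(g * other.data, self.data.shape))
                if other.requires_grad or other._prev:
                    other._accum(_unbroadcast(g * self.data, other.data.shape))
            out._backward = _bw
        return out

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-Tensor._lift(other))

    def __rsub__(self, other):
        return Tensor._lift(other) + (-self)

    def __truediv__(self, other):
        other = Tensor._lift(other)
        return self * other ** -1.0

    def __rtruediv__(self, other):
        return Tensor._lift(other) * self ** -1.0

    def __pow__(self, p: float):
        out = Tensor(self.data ** p, self.requires_grad, (self,))
        if out.requires_grad:
            def _bw(g):
                self._accum(g * p * self.data ** (p - 1.0))
            out._backward = _bw
        return out

    # -- elementwise functions -------------------------------------------
    def exp(self):
        val = np.exp(self.data)
        out = Tensor(val, self.requires_grad, (self,))
        if out.requires_grad:
            out._backward = lambda g: self._accum(g * val)
        return out

    def log(self):
        out = Tensor(np.log(self.data), self.requires_grad, (self,))
        if out.requires_grad:
            out._backward = lambda g: self._accum(g / self.data)
        return out

    def sqrt(self):
        val = np.sqrt(self.data)
        out = Tensor(val, self.requires_grad, (self,))
        if out.requires_grad:
            out._backward = lambda g: self._accum(g * 0.5 / val)
        return out

    def tanh(self):
        val = np.tanh(self.data)
        out = Tensor(val, self.requires_grad, (self,))
        if out.requires_grad:
            out._backward = lambda g: self._accum(g * (1.0 - val * val))
        return out

    def sigmoid(self):
        val = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(val, self.requires_grad, (self,))
        if out.requires_grad:
            out._backward = lambda g: self._accum(g * val * (1.0 - val))
        return out

    def relu(self):
        mask = self.data > 0
        out = Tensor(np.where(mask, self.data, 0.0), self.requires_grad, (self,))
        if out.requires_grad:
            out._backward = lambda g: self._accum(g * mask)
        return out

    def leaky_relu(self, slope: float = 0.2):
        mask = self.data > 0
        out = Tensor(np.where(mask, self.data, slope * self.data),
                     self.requires_grad, (self,))
        if out.requires_grad:
            out._backward = lambda g: self._accum(g * np.where(mask, 1.0, slope))
        return out

    def softplus(self):
        # numerically stable log(1+exp(x))
        val = np.logaddexp(0.0, self.data)
        out = Tensor(val, self.requires_grad, (self,))
        if out.requires_grad:
            sig = 1.0 / (1.0 + np.exp(-self.data))
            out._backward = lambda g: self._accum(g * sig)
        return out

    def silu(self):
        sig = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(self.data * sig, self.requires_grad, (self,))
        if out.requires_grad:
            out._backward = lambda g: self._accum(g * sig * (1.0 + self.data * (1.0 - sig)))
        return out

    def gelu(self):
        x = self.data
        cdf = 0.5 * (1.0 + erf(x / _SQRT2))
        out = Tensor(x * cdf, self.requires_grad, (self,))
        if out.requires_grad:
            pdf = _INV_SQRT2PI * np.exp(-0.5 * x * x)
            out._backward = lambda g: self._accum(g * (cdf + x * pdf))
        return out

    def abs(self):
        sign = np.sign(self.data)
        out = Tensor(np.abs(self.data), self.requires_grad, (self,))
        if out.requires_grad:
            out._backward = lambda g: self._accum(g * sign)
        return out

    # -- reductions -------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims),
                     self.requires_grad, (self,))
        if out.requires_grad:
            def _bw(g):
                if axis is None:
                    self._accum(np.broadcast_to(g, self.data.shape).copy()
                                if np.ndim(g) else np.full_like(self.data, g))
                else:
                    gg = g if keepdims else np.expand_dims(g, axis)
                    self._accum(np.broadcast_to(gg, self.data.shape))
            out._backward = _bw
        return out

    def mean(self, axis=None, keepdims=False):
        if axis is None:
            n = self.data.size
        else:
            axes = (axis,) if isinstance(axis, int) else tuple(axis)
            n = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def max(self, axis: int, keepdims: bool = False):
        idx = np.argmax(self.data, axis=axis)
        val = np.max(self.data, axis=axis, keepdims=keepdims)
        out = Tensor(val, self.requires_grad, (self,))
        if out.requires_grad:
            def _bw(g):
                gg = g if keepdims else np.expand_dims(g, axis)
                grad = np.zeros_like(self.data)
                np.put_along_axis(grad, np.expand_dims(idx, axis),
                                  np.asarray(gg), axis=axis)
                self._accum(grad)
            out._backward = _bw
        return out

    # -- linear algebra ---------------------------------------------------
    def matmul(self, other: "Tensor"):
        other = Tensor._lift(other)
        out = Tensor(self.data @ other.data,
                     self.requires_grad or other.requires_grad, (self, other))
        if out.requires_grad:
            def _bw(g):
                if self.requires_grad or self._prev:
                    ga = g @ np.swapaxes(other.data, -1, -2)
                    self._accum(_unbroadcast(ga, self.data.shape))
                if other.requires_grad or other._prev:
                    gb = np.swapaxes(self.data, -1, -2) @ g
                    other._accum(_unbroadcast(gb, other.data.shape))
            out._backward = _bw
        return out

    __matmul__ = matmul

    # -- shape manipulation ----------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = Tensor(self.data.reshape(shape), self.requires_grad, (self,))
        if out.requires_grad:
            out._backward = lambda g: self._accum(g.reshape(self.data.shape))
        return out

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        out = Tensor(self.data.transpose(axes), self.requires_grad, (self,))
        if out.requires_grad:
            out._backward = lambda g: self._accum(g.transpose(inv))
        return out

    def flip(self, axis: int):
        out = Tensor(np.flip(self.data, axis=axis), self.requires_grad, (self,))
        if out.requires_grad:
            out._backward = lambda g: self._accum(np.flip(g, axis=axis))
        return out

    def __getitem__(self, key):
        out = Tensor(self.data[key], self.requires_grad, (self,))
        if out.requires_grad:
            parts = key if isinstance(key, tuple) else (key,)
            basic = all(isinstance(p, (int, slice, type(None))) for p in parts)
            if basic:
                out._backward = lambda g: self._accum_at(key, g)
            else:
                def _bw(g):
                    grad = np.zeros_like(self.data)
                    np.add.at(grad, key, g)
                    self._accum(grad)
                out._backward = _bw
        return out


# -- free functions -------------------------------------------------------

def concat(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    req = any(t.requires_grad or t._prev for t in tensors)
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                 req, tuple(tensors))
    if req:
        sizes = [t.data.shape[axis] for t in tensors]
        splits = np.cumsum(sizes)[:-1]

        def _bw(g):
            for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
                if t.requires_grad or t._prev:
                    t._accum(piece)
        out._backward = _bw
    return out


def stack(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    req = any(t.requires_grad or t._prev for t in tensors)
    out = Tensor(np.stack([t.data for t in tensors], axis=axis), req, tuple(tensors))
    if req:
        def _bw(g):
            for i, t in enumerate(tensors):
                if t.requires_grad or t._prev:
                    t._accum(np.take(g, i, axis=axis))
        out._backward = _bw
    return out


def conv1d(x: Tensor, w: Tensor, b: Tensor | None = None,
           stride: int = 1, padding: int = 0) -> Tensor:
    """1-D cross-correlation of (B, Cin, L) with weights (Cout, Cin, K)."""
    B, Cin, L = x.data.shape
    Cout, Cin_w, K = w.data.shape
    if Cin != Cin_w:
        raise ValueError(f"channel mismatch: input {Cin}, weight {Cin_w}")
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding))) if padding else x.data
    Lp = xp.shape[2]
    Lout = (Lp - K) // stride + 1
    # cols: (B, Cin, K, Lout) strided view -> (B, Cin*K, Lout)
    win = sliding_window_view(xp, K, axis=2)[:, :, ::stride, :]  # (B,Cin,Lout,K)
    cols = np.ascontiguousarray(win.transpose(0, 1, 3, 2)).reshape(B, Cin * K, Lout)
    W2 = w.data.reshape(Cout, Cin * K)
    val = W2 @ cols
    if b is not None:
        val = val + b.data[:, None]
    prev = (x, w) if b is None else (x, w, b)
    req = any(t.requires_grad or t._prev for t in prev)
    out = Tensor(val, req, prev)
    if req:
        def _bw(g):
            if b is not None and (b.requires_grad or b._prev):
                b._accum(g.sum(axis=(0, 2)))
            if w.requires_grad or w._prev:
                dW2 = np.tensordot(g, cols, axes=([0, 2], [0, 2]))
                w._accum(dW2.reshape(Cout, Cin, K))
            if x.requires_grad or x._prev:
                dcols = (W2.T @ g).reshape(B, Cin, K, Lout)
                dxp = np.zeros((B, Cin, Lp))
                for k in range(K):
                    dxp[:, :, k: k + stride * Lout: stride] += dcols[:, :, k, :]
                x._accum(dxp[:, :, padding: Lp - padding] if padding else dxp)
        out._backward = _bw
    return out


def conv_transpose1d(x: Tensor, w: Tensor, b: Tensor | None = None,
                     stride: int = 1, padding: int = 0,
                     output_padding: int = 0) -> Tensor:
    """Transposed 1-D convolution; weights (Cin, Cout, K)."""
    B, Cin, Lin = x.data.shape
    Cin_w, Cout, K = w.data.shape
    if Cin != Cin_w:
        raise ValueError(f"channel mismatch: input {Cin}, weight {Cin_w}")
    Lfull = (Lin - 1) * stride + K + output_padding
    Lout = (Lin - 1) * stride - 2 * padding + K + output_padding
    W2 = w.data.reshape(Cin, Cout * K)
    tmp = (W2.T @ x.data).reshape(B, Cout, K, Lin)
    yfull = np.zeros((B, Cout, Lfull))
    for k in range(K):
        yfull[:, :, k: k + stride * Lin: stride] += tmp[:, :, k, :]
    val = yfull[:, :, padding: padding + Lout]
    if b is not None:
        val = val + b.data[None, :, None]
    prev = (x, w) if b is None else (x, w, b)
    req = any(t.requires_grad or t._prev for t in prev)
    out = Tensor(val, req, prev)
    if req:
        def _bw(g):
            if b is not None and (b.requires_grad or b._prev):
                b._accum(g.sum(axis=(0, 2)))
            gfull = np.zeros((B, Cout, Lfull))
            gfull[:, :, padding: padding + Lout] = g
            dtmp = np.empty((B, Cout, K, Lin))
            for k in range(K):
                dtmp[:, :, k, :] = gfull[:, :, k: k + stride * Lin: stride]
            dtmp2 = dtmp.reshape(B, Cout * K, Lin)
            if w.requires_grad or w._prev:
                dW2 = np.tensordot(x.data, dtmp2, axes=([0, 2], [0, 2]))
                w._accum(dW2.reshape(Cin, Cout, K))
            if x.requires_grad or x._prev:
                x._accum(W2 @ dtmp2)
        out._backward = _bw
    return out


def upsample_linear2(x: Tensor) -> Tensor:
    """Double the temporal length of (B, C, L) by linear interpolation.

    y[2i] = x[i]; y[2i+1] = (x[i] + x[i+1]) / 2, clamping at the right edge.
    """
    B, C, L = x.data.shape
    val = np.empty((B, C, 2 * L))
    val[:, :, 0::2] = x.data
    shifted = np.concatenate([x.data[:, :, 1:], x.data[:, :, -1:]], axis=2)
    val[:, :, 1::2] = 0.5 * (x.data + shifted)
    req = x.requires_grad or bool(x._prev)
    out = Tensor(val, req, (x,))
    if req:
        def _bw(g):
            ge, go = g[:, :, 0::2], g[:, :, 1::2]
            dx = ge + 0.5 * go
            dx[:, :, 1:] += 0.5 * go[:, :, :-1]
            dx[:, :, -1] += 0.5 * go[:, :, -1]
            x._accum(dx)
        out._backward = _bw
    return out
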