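"""Reverse-mode automatic differentiation over NumPy arrays.

A deliberately small tape-based engine: enough ops for the convolutional
segmentation and detection models in this package (convolution with stride
and dilation, elementwise arithmetic with broadcasting, reductions, nearest
upsampling, concatenation, matmul, and the fused classification losses).
Everything is float64 NumPy, single-threaded and deterministic.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "conv2d", "upsample_nearest2d"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of NumPy broadcasting)."""
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
    """Array node in the autodiff graph."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward = None
        self._prev: tuple[Tensor, ...] = ()

    # -- graph plumbing ---------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = grad.copy()
        else:
            self.grad += grad

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient needs a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
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
            for p in node._prev:
                if id(p) not in seen:
                    stack.append((p, False))
        self._accumulate(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_grad(self) -> None:
        self.grad = None

    # -- op helpers -------------------------------------------------------
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def _make(self, data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad or p._prev for p in parents):
            out.requires_grad = True
            out._prev = tuple(parents)
            out._backward = backward
        return out

    # -- elementwise ------------------------------------------------------
    def __add__(self, other):
        other = self._lift(other)

        def backward(g):
            self._accumulate(_unbroadcast(g, self.data.shape))
            other._accumulate(_unbroadcast(g, other.data.shape))

        return self._make(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            self._accumulate(-g)

        return self._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)

        def backward(g):
            self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            other._accumulate(_unbroadcast(g * self.data, other.data.shape))

        return self._make(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)

        def backward(g):
            self._accumulate(_unbroadcast(g / other.data, self.data.shape))
            other._accumulate(
                _unbroadcast(-g * self.data / (other.data**2), other.data.shape)
            )

        return self._make(self.data / other.data, (self, other), backward)

    def pow_const(self, p: float):
        def backward(g):
            self._accumulate(g * p * self.data ** (p - 1))

        return self._make(self.data**p, (self,), backward)

    def sqrt(self):
        out_data = np.sqrt(self.data)

        def backward(g):
            self._accumulate(g * 0.5 / np.maximum(out_data, 1e-30))

        return self._make(out_data, (self,), backward)

    def exp(self):
        out_data = np.exp(self.data)

        def backward(g):
            self._accumulate(g * out_data)

        return self._make(out_data, (self,), backward)

    def log(self):
        def backward(g):
            self._accumulate(g / self.data)

        return self._make(np.log(self.data), (self,), backward)

    def relu(self):
        mask = self.data > 0

        def backward(g):
            self._accumulate(g * mask)

        return self._make(self.data * mask, (self,), backward)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-np.clip(self.data, -60, 60)))

        def backward(g):
            self._accumulate(g * out_data * (1.0 - out_data))

        return self._make(out_data, (self,), backward)

    def abs(self):
        sign = np.sign(self.data)

        def backward(g):
            self._accumulate(g * sign)

        return self._make(np.abs(self.data), (self,), backward)

    # -- reductions / shape ----------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        def backward(g):
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.data.shape).copy())
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.data.shape).copy())

        return self._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape):
        orig = self.data.shape

        def backward(g):
            self._accumulate(g.reshape(orig))

        return self._make(self.data.reshape(*shape), (self,), backward)

    def transpose(self, *axes):
        inv = np.argsort(axes)

        def backward(g):
            self._accumulate(g.transpose(inv))

        return self._make(self.data.transpose(axes), (self,), backward)

    def __getitem__(self, key):
        def backward(g):
            full = np.zeros_like(self.data)
            np.add.at(full, key, g)
            self._accumulate(full)

        return self._make(self.data[key], (self,), backward)

    def matmul(self, other: "Tensor"):
        other = self._lift(other)

        def backward(g):
            self._accumulate(g @ other.data.swapaxes(-1, -2))
            other._accumulate(self.data.swapaxes(-1, -2) @ g)

        return self._make(self.data @ other.data, (self, other), backward)

    __matmul__ = matmul


def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    """Concatenate tensors along an axis."""
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            t._accumulate(piece)

    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis))
    if any(t.requires_grad or t._prev for t in tensors):
        out.requires_grad = True
        out._prev = tuple(tensors)
        out._backward = backward
    return out


def _im2col_indices(c, h, w, kh, kw, stride, dilation, out_h, out_w):
    """Index arrays mapping padded input to columns (cs231n layout)."""
    i0 = np.repeat(np.arange(kh) * dilation, kw)
    i0 = np.tile(i0, c)
    i1 = stride * np.repeat(np.arange(out_h), out_w)
    j0 = np.tile(np.arange(kw) * dilation, kh * c)
    j1 = stride * np.tile(np.arange(out_w), out_h)
    i = i0.reshape(-1, 1) + i1.reshape(1, -1)
    j = j0.reshape(-1, 1) + j1.reshape(1, -1)
    k = np.repeat(np.arange(c), kh * kw).reshape(-1, 1)
    return k, i, j


def conv2d(
    x: Tensor,
    weight: Tensor,
    bias: Tensor | None = None,
    stride: int = 1,
    dilation: int = 1,
    padding: int | None = None,
) -> Tensor:
    """2D convolution (cross-correlation) over NCHW input with zero padding.

    ``padding=None`` picks "same" padding for stride 1:
    ``dilation * (k - 1) // 2``.
    """
    n, c, h, w = x.data.shape
    f, c2, kh, kw = weight.data.shape
    if c != c2:
        raise ValueError(f"channel mismatch: input {c}, weight expects {c2}")
    if padding is None:
        padding = dilation * (kh - 1) // 2
    eff_h = dilation * (kh - 1) + 1
    eff_w = dilation * (kw - 1) + 1
    out_h = (h + 2 * padding - eff_h) // stride + 1
    out_w = (w + 2 * padding - eff_w) // stride + 1
    if out_h <= 0 or out_w <= 0:
        raise ValueError(
            f"input {h}x{w} too small for kernel {kh} dilation {dilation} padding {padding}"
        )
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    k, i, j = _im2col_indices(c, h, w, kh, kw, stride, dilation, out_h, out_w)
    cols = xp[:, k, i, j]  # (n, c*kh*kw, out_h*out_w)
    w_row = weight.data.reshape(f, -1)
    out_data = np.einsum("fk,nkp->nfp", w_row, cols).reshape(n, f, out_h, out_w)
    if bias is not None:
        out_data = out_data + bias.data.reshape(1, f, 1, 1)

    parents = (x, weight) if bias is None else (x, weight, bias)

    def backward(g):
        gf = g.reshape(n, f, -1)  # (n, f, P)
        weight._accumulate(
            np.einsum("nfp,nkp->fk", gf, cols).reshape(weight.data.shape)
        )
        if bias is not None:
            bias._accumulate(g.sum(axis=(0, 2, 3)))
        gcols = np.einsum("fk,nfp->nkp", w_row, gf)
        gxp = np.zeros_like(xp)
        np.add.at(gxp, (slice(None), k, i, j), gcols)
        if padding:
            gx = gxp[:, :, padding:-padding, padding:-padding]
        else:
            gx = gxp
        x._accumulate(gx)

    out = Tensor(out_data)
    if any(p.requires_grad or p._prev for p in parents):
        out.requires_grad = True
        out._prev = parents
        out._backward = backward
    return out


def upsample_nearest2d(x: Tensor, factor: int = 2) -> Tensor:
    """Nearest-neighbour upsampling by an integer factor on NCHW input."""
    n, c, h, w = x.data.shape
    out_data = x.data.repeat(factor, axis=2).repeat(factor, axis=3)

    def backward(g):
        gr = g.reshape(n, c, h, factor, w, factor).sum(axis=(3, 5))
        x._accumulate(gr)

    out = Tensor(out_data)
    if x.requires_grad or x._prev:
        out.requires_grad = True
        out._prev = (x,)
        out._backward = backward
    return out
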