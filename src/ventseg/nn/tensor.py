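"""Minimal reverse-mode automatic differentiation on numpy arrays.

Only the operations the 1-D U-Net needs are implemented: elementwise
arithmetic with broadcasting, matmul, reductions, reshaping/slicing/concat,
the activations used by the network, 1-D convolution (stride 1, arbitrary
dilation, 'same' padding), stride-2 transposed convolution, and stride-2 max
pooling.  Gradients accumulate on every node, which Grad-CAM exploits to read
the gradient of a logit with respect to an intermediate feature map.
"""

from __future__ import annotations

import numpy as np
from scipy.special import erf

__all__ = ["Tensor", "concat", "conv1d", "conv_transpose1d", "maxpool1d"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (reverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.grad = None
        self.requires_grad = requires_grad
        self._parents: tuple = ()
        self._backward = None

    # -- graph plumbing ----------------------------------------------------

    @staticmethod
    def _make(data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = parents
            out._backward = backward
        return out

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data, dtype=g.dtype)
        self.grad = self.grad + g

    def backward(self, grad=None) -> None:
        """Backpropagate from this node (default seed: ones)."""
        topo, seen = [], set()

        def visit(node):
            if id(node) in seen:
                return
            seen.add(id(node))
            for p in node._parents:
                visit(p)
            topo.append(node)

        visit(self)
        if grad is None:
            grad = np.ones_like(self.data)
        self._accumulate(np.asarray(grad, dtype=self.data.dtype))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_grad(self) -> None:
        self.grad = None

    # -- basic properties --------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # -- elementwise arithmetic --------------------------------------------

    @staticmethod
    def _coerce(x, dtype=None) -> "Tensor":
        if isinstance(x, Tensor):
            return x
        # python scalars adopt the partner's dtype so float32 graphs stay float32
        if dtype is not None and np.isscalar(x):
            return Tensor(np.asarray(x, dtype=dtype))
        return Tensor(np.asarray(x))

    def __add__(self, other):
        other = Tensor._coerce(other, self.data.dtype)

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.shape))

        return Tensor._make(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            if self.requires_grad:
                self._accumulate(-g)

        return Tensor._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-Tensor._coerce(other, self.data.dtype))

    def __rsub__(self, other):
        return Tensor._coerce(other, self.data.dtype) + (-self)

    def __mul__(self, other):
        other = Tensor._coerce(other, self.data.dtype)

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.shape))

        return Tensor._make(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor._coerce(other, self.data.dtype)
        return self * other ** -1.0

    def __rtruediv__(self, other):
        return Tensor._coerce(other, self.data.dtype) * self ** -1.0

    def __pow__(self, exponent: float):
        e = float(exponent)
        out_data = self.data ** e

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * e * self.data ** (e - 1.0))

        return Tensor._make(out_data, (self,), backward)

    def exp(self):
        out_data = np.exp(self.data)

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * out_data)

        return Tensor._make(out_data, (self,), backward)

    def log(self):
        def backward(g):
            if self.requires_grad:
                self._accumulate(g / self.data)

        return Tensor._make(np.log(self.data), (self,), backward)

    def sqrt(self):
        return self ** 0.5

    def clip(self, lo: float, hi: float):
        """Clamp values; gradient passes only through the interior."""
        mask = (self.data > lo) & (self.data < hi)

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * mask)

        return Tensor._make(np.clip(self.data, lo, hi), (self,), backward)

    # -- activations -------------------------------------------------------

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * out_data * (1.0 - out_data))

        return Tensor._make(out_data, (self,), backward)

    def relu(self):
        mask = self.data > 0

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * mask)

        return Tensor._make(self.data * mask, (self,), backward)

    def leaky_relu(self, slope: float = 0.01):
        factor = np.where(self.data > 0, 1.0, slope).astype(self.data.dtype)

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * factor)

        return Tensor._make(self.data * factor, (self,), backward)

    def gelu(self):
        """Exact GELU: x·Φ(x) with Φ the standard normal CDF."""
        x = self.data
        cdf = 0.5 * (1.0 + erf(x / 1.4142135623730951))
        pdf = np.exp(-0.5 * x * x) * 0.3989422804014327  # 1/sqrt(2*pi)

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * (cdf + x * pdf))

        return Tensor._make(x * cdf, (self,), backward)

    # -- reductions / shaping ----------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.shape).copy())
                return
            axes = (axis,) if isinstance(axis, int) else tuple(axis)
            if not keepdims:
                for ax in sorted(ax % self.ndim for ax in axes):
                    g = np.expand_dims(g, ax)
            self._accumulate(np.broadcast_to(g, self.shape).copy())

        return Tensor._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = (axis,) if isinstance(axis, int) else tuple(axis)
            n = int(np.prod([self.shape[ax] for ax in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        old = self.shape

        def backward(g):
            if self.requires_grad:
                self._accumulate(g.reshape(old))

        return Tensor._make(self.data.reshape(*shape), (self,), backward)

    def transpose(self, *axes):
        inverse = np.argsort(axes)

        def backward(g):
            if self.requires_grad:
                self._accumulate(g.transpose(*inverse))

        return Tensor._make(self.data.transpose(*axes), (self,), backward)

    def __getitem__(self, key):
        def backward(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.add.at(full, key, g)
                self._accumulate(full)

        return Tensor._make(self.data[key], (self,), backward)

    def __matmul__(self, other):
        other = Tensor._coerce(other)

        def backward(g):
            if self.requires_grad:
                self._accumulate(g @ other.data.T)
            if other.requires_grad:
                other._accumulate(self.data.T @ g)

        return Tensor._make(self.data @ other.data, (self, other), backward)


def concat(tensors, axis: int = -1) -> Tensor:
    tensors = [Tensor._coerce(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            if t.requires_grad:
                t._accumulate(piece)

    return Tensor._make(
        np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors), backward
    )


def conv1d(x: Tensor, w: Tensor, b: Tensor | None = None, dilation: int = 1) -> Tensor:
    """1-D convolution, stride 1, 'same' zero padding.

    x: (N, L, C_in); w: (K, C_in, C_out); b: (C_out,). Output (N, L, C_out).
    Implemented as im2col + matmul so BLAS does the heavy lifting.
    """
    xd = x.data
    n, length, c_in = xd.shape
    k, wc_in, c_out = w.shape
    if wc_in != c_in:
        raise ValueError(f"conv1d channel mismatch: input {c_in}, weight {wc_in}")
    pad = dilation * (k - 1) // 2
    xp = np.pad(xd, ((0, 0), (pad, pad), (0, 0)))
    cols = np.empty((n, length, k, c_in), dtype=xd.dtype)
    for j in range(k):
        cols[:, :, j, :] = xp[:, j * dilation : j * dilation + length, :]
    cols2 = cols.reshape(n * length, k * c_in)
    w2 = w.data.reshape(k * c_in, c_out)
    out = cols2 @ w2
    if b is not None:
        out = out + b.data
    out = out.reshape(n, length, c_out)
    parents = (x, w) if b is None else (x, w, b)

    def backward(g):
        g2 = g.reshape(n * length, c_out)
        if w.requires_grad:
            w._accumulate((cols2.T @ g2).reshape(k, c_in, c_out))
        if b is not None and b.requires_grad:
            b._accumulate(g2.sum(axis=0))
        if x.requires_grad:
            dcols = (g2 @ w2.T).reshape(n, length, k, c_in)
            dxp = np.zeros_like(xp)
            for j in range(k):
                dxp[:, j * dilation : j * dilation + length, :] += dcols[:, :, j, :]
            x._accumulate(dxp[:, pad : pad + length, :])

    return Tensor._make(out, parents, backward)


def conv_transpose1d(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """Stride-2, kernel-2 transposed convolution (exact 2x upsampling).

    x: (N, L, C_in); w: (2, C_in, C_out); output (N, 2L, C_out).
    """
    xd = x.data
    n, length, c_in = xd.shape
    k, wc_in, c_out = w.shape
    if k != 2 or wc_in != c_in:
        raise ValueError("conv_transpose1d expects weight shape (2, C_in, C_out)")
    x2 = xd.reshape(n * length, c_in)
    w2 = w.data.transpose(1, 0, 2).reshape(c_in, k * c_out)
    out = (x2 @ w2).reshape(n, length * k, c_out)
    if b is not None:
        out = out + b.data
    parents = (x, w) if b is None else (x, w, b)

    def backward(g):
        g2 = g.reshape(n * length, k * c_out)
        if w.requires_grad:
            w._accumulate((x2.T @ g2).reshape(c_in, k, c_out).transpose(1, 0, 2))
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=(0, 1)))
        if x.requires_grad:
            x._accumulate((g2 @ w2.T).reshape(n, length, c_in))

    return Tensor._make(out, parents, backward)


def maxpool1d(x: Tensor, size: int = 2) -> Tensor:
    """Non-overlapping max pooling; length must be divisible by `size`."""
    xd = x.data
    n, length, c = xd.shape
    if length % size:
        raise ValueError(f"maxpool1d: length {length} not divisible by {size}")
    xr = xd.reshape(n, length // size, size, c)
    idx = xr.argmax(axis=2)
    out = xr.max(axis=2)

    def backward(g):
        if not x.requires_grad:
            return
        onehot = idx[:, :, None, :] == np.arange(size)[None, None, :, None]
        x._accumulate((onehot * g[:, :, None, :]).reshape(n, length, c))

    return Tensor._make(out, (x,), backward)
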