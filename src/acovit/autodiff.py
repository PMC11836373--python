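"""Minimal reverse-mode automatic differentiation over NumPy arrays.

A ``Tensor`` wraps a floating ndarray and records its parents plus a
backward closure; ``Tensor.backward()`` runs reverse-mode accumulation over
the topologically sorted graph. The op set is exactly what the
windowed-attention transformer needs: broadcasting arithmetic, matmul,
two-operand ``einsum`` contractions, exp/log/erf-based GELU, reductions,
reshapes, fancy gathers (``take``) and concatenation. Gradients are
verified against central finite differences in the test suite.

Tensors keep the dtype they are given (float32 for training nets, float64
where oracle comparisons and finite-difference checks need it); python
scalars adopt the tensor's dtype so mixed expressions never upcast.
Gradient accumulation stores the first contribution by reference and adds
out-of-place afterwards — backward closures only ever produce fresh arrays
or read-only views, so no buffer is mutated after being handed over.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from scipy.special import erf

__all__ = ["Tensor", "concat", "einsum", "softmax", "layer_norm", "gelu"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum-reduce ``grad`` back to ``shape`` after a broadcast op."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, (g, s) in enumerate(zip(grad.shape, shape)):
        if s == 1 and g != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "_parents", "_bwd")

    def __init__(self, data, parents: tuple = (), bwd=None):
        arr = np.asarray(data)
        if not np.issubdtype(arr.dtype, np.floating):
            arr = arr.astype(np.float64)
        self.data = arr
        self.grad: np.ndarray | None = None
        self._parents = parents
        self._bwd = bwd

    # -- graph bookkeeping ----------------------------------------------------

    def _accumulate(self, grad: np.ndarray) -> None:
        # first contribution by reference; later ones add out-of-place
        self.grad = grad if self.grad is None else self.grad + grad

    def backward(self) -> None:
        """Reverse-mode accumulation from this (typically scalar) tensor."""
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
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._bwd is not None and node.grad is not None:
                node._bwd(node.grad)

    @property
    def shape(self):
        return self.data.shape

    # -- arithmetic -----------------------------------------------------------

    def _wrap(self, other) -> "Tensor":
        if isinstance(other, Tensor):
            return other
        # scalars adopt this tensor's dtype so expressions never upcast
        return Tensor(np.asarray(other, dtype=self.data.dtype))

    def __add__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data + other.data, (self, other))

        def bwd(g):
            self._accumulate(_unbroadcast(g, self.data.shape))
            other._accumulate(_unbroadcast(g, other.data.shape))

        out._bwd = bwd
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, (self,))
        out._bwd = lambda g: self._accumulate(-g)
        return out

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data * other.data, (self, other))

        def bwd(g):
            self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            other._accumulate(_unbroadcast(g * self.data, other.data.shape))

        out._bwd = bwd
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        return self * self._wrap(other) ** -1.0

    def __rtruediv__(self, other):
        return self._wrap(other) * self**-1.0

    def __pow__(self, exponent: float):
        out = Tensor(self.data**exponent, (self,))

        def bwd(g):
            self._accumulate(g * exponent * self.data ** (exponent - 1.0))

        out._bwd = bwd
        return out

    def __matmul__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data @ other.data, (self, other))

        def bwd(g):
            a, b = self.data, other.data
            ga = g @ np.swapaxes(b, -1, -2) if b.ndim > 1 else np.outer(g, b)
            gb = np.swapaxes(a, -1, -2) @ g if a.ndim > 1 else np.outer(a, g)
            self._accumulate(_unbroadcast(ga, a.shape))
            other._accumulate(_unbroadcast(gb, b.shape))

        out._bwd = bwd
        return out

    # -- elementwise ----------------------------------------------------------

    def exp(self):
        out = Tensor(np.exp(self.data), (self,))
        out._bwd = lambda g: self._accumulate(g * out.data)
        return out

    def log(self):
        out = Tensor(np.log(self.data), (self,))
        out._bwd = lambda g: self._accumulate(g / self.data)
        return out

    # -- reductions / shaping -------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), (self,))

        def bwd(g):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            # read-only broadcast view; accumulation never writes in place
            self._accumulate(np.broadcast_to(g, self.data.shape))

        out._bwd = bwd
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), (self,))
        out._bwd = lambda g: self._accumulate(g.reshape(self.data.shape))
        return out

    def transpose(self, axes: Sequence[int]):
        inv = np.argsort(axes)
        out = Tensor(self.data.transpose(axes), (self,))
        out._bwd = lambda g: self._accumulate(g.transpose(inv))
        return out

    def take(self, indices: np.ndarray, axis: int):
        """Fancy gather along ``axis``; backward scatter-adds."""
        idx = np.asarray(indices)
        out = Tensor(np.take(self.data, idx, axis=axis), (self,))

        def bwd(g):
            gx = np.zeros_like(self.data)
            np.add.at(gx, (slice(None),) * axis + (idx,), g)
            self._accumulate(gx)

        out._bwd = bwd
        return out


def einsum(spec: str, a: Tensor, b: Tensor) -> Tensor:
    """Two-operand einsum without ellipsis or repeated in-operand indices.

    Every index of each operand must appear in the output or in the other
    operand (true for attention contractions), so each backward pass is
    itself a single einsum and no broadcast temporaries are materialized.
    """
    ins, out_spec = spec.replace(" ", "").split("->")
    sa, sb = ins.split(",")
    out = Tensor(np.einsum(spec, a.data, b.data), (a, b))

    def bwd(g):
        a._accumulate(np.einsum(f"{out_spec},{sb}->{sa}", g, b.data))
        b._accumulate(np.einsum(f"{sa},{out_spec}->{sb}", a.data, g))

    out._bwd = bwd
    return out


def concat(tensors: Sequence[Tensor], axis: int = -1) -> Tensor:
    datas = [t.data for t in tensors]
    out = Tensor(np.concatenate(datas, axis=axis), tuple(tensors))
    sizes = [d.shape[axis] for d in datas]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            t._accumulate(g[tuple(sl)])

    out._bwd = bwd
    return out


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    """Numerically stable softmax (the shift by the detached max has zero grad)."""
    shift = Tensor(x.data.max(axis=axis, keepdims=True))
    e = (x - shift).exp()
    return e / e.sum(axis=axis, keepdims=True)


def layer_norm(x: Tensor, gain: Tensor, bias: Tensor, eps: float = 1e-5) -> Tensor:
    """Layer normalization over the last axis."""
    mu = x.mean(axis=-1, keepdims=True)
    xc = x - mu
    var = (xc * xc).mean(axis=-1, keepdims=True)
    return xc * (var + eps) ** -0.5 * gain + bias


def gelu(x: Tensor) -> Tensor:
    """Exact (erf-based) Gaussian error linear unit."""
    dt = x.data.dtype
    cdf = (0.5 * (1.0 + erf(x.data / np.sqrt(2.0)))).astype(dt, copy=False)
    out = Tensor(x.data * cdf, (x,))
    pdf = (np.exp(-0.5 * x.data**2) / np.sqrt(2.0 * np.pi)).astype(dt, copy=False)
    out._bwd = lambda g: x._accumulate(g * (cdf + x.data * pdf))
    return out
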