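"""Minimal reverse-mode automatic differentiation over numpy arrays.

A small tape-based engine: :class:`Tensor` wraps an ``ndarray``, records the
operations applied to it, and :meth:`Tensor.backward` replays the tape in
reverse topological order. The op set is exactly what the dynamics network
needs — broadcasting arithmetic, batched matmul, reductions, shape ops,
softplus/sigmoid/relu, indexing, concatenation — plus one domain-specific
primitive, :func:`spd_log`, the principal matrix logarithm of batched SPD
matrices with the Daleckii–Krein closed-form backward pass.

Gradients are accumulated in float64. Everything is single-threaded and
deterministic.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concatenate", "stack", "spd_log", "softmax"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


def _as_tensor(x) -> "Tensor":
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=float))


class Tensor:
    __slots__ = ("data", "requires_grad", "grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=float)
        self.requires_grad = bool(requires_grad)
        self.grad = None
        self._backward = None
        self._parents: tuple = ()

    # ----- bookkeeping -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def _accum(self, g: np.ndarray):
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    @staticmethod
    def _make(data, parents, backward) -> "Tensor":
        out = Tensor(data, requires_grad=any(p.requires_grad for p in parents))
        if out.requires_grad:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar output")
            grad = np.ones_like(self.data)
        # topological order over the tape
        topo, seen = [], set()

        def visit(t: "Tensor"):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self._accum(np.asarray(grad, dtype=float))
        for t in reversed(topo):
            if t._backward is not None:
                t._backward(t.grad)

    # ----- arithmetic --------------------------------------------------
    def __add__(self, other):
        a, b = self, _as_tensor(other)
        out_data = a.data + b.data

        def bw(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g, a.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g, b.shape))

        return Tensor._make(out_data, (a, b), bw)

    __radd__ = __add__

    def __neg__(self):
        a = self

        def bw(g):
            if a.requires_grad:
                a._accum(-g)

        return Tensor._make(-a.data, (a,), bw)

    def __sub__(self, other):
        return self + (-_as_tensor(other))

    def __rsub__(self, other):
        return _as_tensor(other) + (-self)

    def __mul__(self, other):
        a, b = self, _as_tensor(other)

        def bw(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g * b.data, a.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g * a.data, b.shape))

        return Tensor._make(a.data * b.data, (a, b), bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        a, b = self, _as_tensor(other)

        def bw(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g / b.data, a.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(-g * a.data / (b.data**2), b.shape))

        return Tensor._make(a.data / b.data, (a, b), bw)

    def __rtruediv__(self, other):
        return _as_tensor(other) / self

    def __pow__(self, p: float):
        a = self
        if not np.isscalar(p):
            raise TypeError("only scalar exponents are supported")

        def bw(g):
            if a.requires_grad:
                a._accum(g * p * a.data ** (p - 1))

        return Tensor._make(a.data**p, (a,), bw)

    def __matmul__(self, other):
        a, b = self, _as_tensor(other)
        out_data = a.data @ b.data

        def bw(g):
            if a.requires_grad:
                ga = g @ np.swapaxes(b.data, -1, -2)
                a._accum(_unbroadcast(ga, a.shape))
            if b.requires_grad:
                gb = np.swapaxes(a.data, -1, -2) @ g
                b._accum(_unbroadcast(gb, b.shape))

        return Tensor._make(out_data, (a, b), bw)

    # ----- elementwise nonlinearities ----------------------------------
    def exp(self):
        a = self
        out_data = np.exp(a.data)

        def bw(g):
            if a.requires_grad:
                a._accum(g * out_data)

        return Tensor._make(out_data, (a,), bw)

    def log(self):
        a = self

        def bw(g):
            if a.requires_grad:
                a._accum(g / a.data)

        return Tensor._make(np.log(a.data), (a,), bw)

    def sqrt(self):
        a = self
        out_data = np.sqrt(a.data)

        def bw(g):
            if a.requires_grad:
                a._accum(g * 0.5 / out_data)

        return Tensor._make(out_data, (a,), bw)

    def relu(self):
        a = self
        mask = a.data > 0

        def bw(g):
            if a.requires_grad:
                a._accum(g * mask)

        return Tensor._make(a.data * mask, (a,), bw)

    def sigmoid(self):
        a = self
        out_data = 0.5 * (1.0 + np.tanh(0.5 * a.data))

        def bw(g):
            if a.requires_grad:
                a._accum(g * out_data * (1.0 - out_data))

        return Tensor._make(out_data, (a,), bw)

    def softplus(self):
        """ln(1 + e^x), stable for large |x|; derivative is the sigmoid."""
        a = self
        out_data = np.maximum(a.data, 0.0) + np.log1p(np.exp(-np.abs(a.data)))
        sig = 0.5 * (1.0 + np.tanh(0.5 * a.data))

        def bw(g):
            if a.requires_grad:
                a._accum(g * sig)

        return Tensor._make(out_data, (a,), bw)

    # ----- reductions & shape ops --------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        a = self
        out_data = a.data.sum(axis=axis, keepdims=keepdims)

        def bw(g):
            if not a.requires_grad:
                return
            if axis is None:
                a._accum(np.broadcast_to(g, a.shape).copy())
                return
            gg = g
            if not keepdims:
                gg = np.expand_dims(gg, axis)
            a._accum(np.broadcast_to(gg, a.shape).copy())

        return Tensor._make(out_data, (a,), bw)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else (
            np.prod([self.shape[ax] for ax in np.atleast_1d(axis)])
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape):
        a = self
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        orig = a.shape

        def bw(g):
            if a.requires_grad:
                a._accum(g.reshape(orig))

        return Tensor._make(a.data.reshape(shape), (a,), bw)

    def transpose(self, axes):
        a = self
        axes = tuple(axes)
        inv = tuple(np.argsort(axes))

        def bw(g):
            if a.requires_grad:
                a._accum(g.transpose(inv))

        return Tensor._make(a.data.transpose(axes), (a,), bw)

    @property
    def mT(self):
        """Swap the last two axes (batched matrix transpose)."""
        nd = self.ndim
        axes = list(range(nd))
        axes[-1], axes[-2] = axes[-2], axes[-1]
        return self.transpose(axes)

    def __getitem__(self, idx):
        a = self
        out_data = a.data[idx]

        def bw(g):
            if a.requires_grad:
                full = np.zeros_like(a.data)
                np.add.at(full, idx, g)
                a._accum(full)

        return Tensor._make(out_data, (a,), bw)


def concatenate(tensors, axis: int = -1) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, s, e in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(s, e)
                t._accum(g[tuple(sl)])

    return Tensor._make(out_data, tuple(tensors), bw)


def stack(tensors, axis: int = 0) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    out_data = np.stack([t.data for t in tensors], axis=axis)

    def bw(g):
        for k, t in enumerate(tensors):
            if t.requires_grad:
                t._accum(np.take(g, k, axis=axis))

    return Tensor._make(out_data, tuple(tensors), bw)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    """Softmax along ``axis`` (shift by a detached max for stability)."""
    m = Tensor(np.max(x.data, axis=axis, keepdims=True))
    e = (x - m).exp()
    return e / e.sum(axis=axis, keepdims=True)


def spd_log(x: Tensor, eig_floor: float = 1e-12) -> Tensor:
    """Principal matrix logarithm of batched SPD matrices (..., d, d).

    Forward: symmetric eigendecomposition. Backward: the Fréchet derivative
    of the matrix logarithm in the eigenbasis is elementwise multiplication
    by the Loewner matrix ``K_ij = (log w_i - log w_j) / (w_i - w_j)``
    (``1/w_i`` on the diagonal / for coincident eigenvalues), so

        grad_in = Q (K ∘ (Q^T grad_out_sym Q)) Q^T.
    """
    a = x
    M = 0.5 * (a.data + np.swapaxes(a.data, -1, -2))
    w, Q = np.linalg.eigh(M)
    if np.any(w < eig_floor):
        raise ValueError(
            f"spd_log: eigenvalue {w.min():.3e} below floor {eig_floor:.0e}"
        )
    logw = np.log(w)
    out_data = (Q * logw[..., None, :]) @ np.swapaxes(Q, -1, -2)

    def bw(g):
        if not a.requires_grad:
            return
        gs = 0.5 * (g + np.swapaxes(g, -1, -2))
        dw = w[..., :, None] - w[..., None, :]
        dlog = logw[..., :, None] - logw[..., None, :]
        near = np.abs(dw) < 1e-12
        dw_safe = np.where(near, 1.0, dw)
        K = np.where(near, 1.0 / w[..., :, None] + 0.0 * dw, dlog / dw_safe)
        inner = np.swapaxes(Q, -1, -2) @ gs @ Q
        grad = Q @ (K * inner) @ np.swapaxes(Q, -1, -2)
        a._accum(0.5 * (grad + np.swapaxes(grad, -1, -2)))

    return Tensor._make(out_data, (a,), bw)
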