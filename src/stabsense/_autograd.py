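"""Minimal reverse-mode automatic differentiation on numpy arrays.

A small tape-based autodiff core sufficient for the three neural models in
this package (autoencoder, diffusion denoiser, attentive classifier). Only
the operations those models need are implemented; gradients are accumulated
into ``Tensor.grad`` by :meth:`Tensor.backward` in reverse topological
order. Broadcasting follows numpy semantics; gradients of broadcast
operands are summed back to the operand's shape.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "sparsemax_t", "bce_with_logits", "softmax_cross_entropy", "no_grad"]

_GRAD_ENABLED = True


class no_grad:
    """Context manager disabling graph construction (inference mode).

    Inside the context no operation records parents or backward closures,
    so intermediates are freed as soon as they go out of scope.
    """

    def __enter__(self):
        global _GRAD_ENABLED
        self._prev_state = _GRAD_ENABLED
        _GRAD_ENABLED = False
        return self

    def __exit__(self, *exc):
        global _GRAD_ENABLED
        _GRAD_ENABLED = self._prev_state
        return False


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """An array node on the autodiff tape."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._prev = ()

    @property
    def shape(self):
        return self.data.shape

    # -- graph construction helpers -------------------------------------
    @staticmethod
    def _lift(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def _make(self, data, prev, backward) -> "Tensor":
        out = Tensor(data)
        out.requires_grad = _GRAD_ENABLED and any(p.requires_grad for p in prev)
        if out.requires_grad:
            out._prev = tuple(prev)
        return out

    def _accum(self, grad):
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += _unbroadcast(grad, self.data.shape)

    # -- arithmetic ------------------------------------------------------
    def __add__(self, other):
        other = self._lift(other)
        out = self._make(self.data + other.data, (self, other), None)

        def backward(g):
            if self.requires_grad:
                self._accum(g)
            if other.requires_grad:
                other._accum(g)

        if out.requires_grad:
            out._backward = backward
        return out

    __radd__ = __add__

    def __neg__(self):
        return self * -1.0

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out = self._make(self.data * other.data, (self, other), None)

        def backward(g):
            if self.requires_grad:
                self._accum(g * other.data)
            if other.requires_grad:
                other._accum(g * self.data)

        if out.requires_grad:
            out._backward = backward
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        return self * other ** -1.0

    def __rtruediv__(self, other):
        return self._lift(other) * self ** -1.0

    def __pow__(self, p: float):
        out = self._make(self.data ** p, (self,), None)

        def backward(g):
            if self.requires_grad:
                self._accum(g * p * self.data ** (p - 1))

        if out.requires_grad:
            out._backward = backward
        return out

    def __matmul__(self, other):
        other = self._lift(other)
        out = self._make(self.data @ other.data, (self, other), None)

        def backward(g):
            if self.requires_grad:
                self._accum(g @ other.data.T)
            if other.requires_grad:
                other._accum(self.data.T @ g)

        if out.requires_grad:
            out._backward = backward
        return out

    # -- elementwise nonlinearities ---------------------------------------
    def relu(self):
        mask = self.data > 0
        out = self._make(np.where(mask, self.data, 0.0), (self,), None)

        def backward(g):
            if self.requires_grad:
                self._accum(g * mask)

        if out.requires_grad:
            out._backward = backward
        return out

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-np.clip(self.data, -60, 60)))
        out = self._make(s, (self,), None)

        def backward(g):
            if self.requires_grad:
                self._accum(g * s * (1 - s))

        if out.requires_grad:
            out._backward = backward
        return out

    def tanh(self):
        t = np.tanh(self.data)
        out = self._make(t, (self,), None)

        def backward(g):
            if self.requires_grad:
                self._accum(g * (1 - t * t))

        if out.requires_grad:
            out._backward = backward
        return out

    def exp(self):
        e = np.exp(np.clip(self.data, -700, 700))
        out = self._make(e, (self,), None)

        def backward(g):
            if self.requires_grad:
                self._accum(g * e)

        if out.requires_grad:
            out._backward = backward
        return out

    def log(self):
        out = self._make(np.log(self.data), (self,), None)

        def backward(g):
            if self.requires_grad:
                self._accum(g / self.data)

        if out.requires_grad:
            out._backward = backward
        return out

    def sqrt(self):
        return self ** 0.5

    # -- reductions / shape -----------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out = self._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), None)

        def backward(g):
            if self.requires_grad:
                gg = np.asarray(g)
                if axis is not None and not keepdims:
                    gg = np.expand_dims(gg, axis)
                self._accum(np.broadcast_to(gg, self.data.shape))

        if out.requires_grad:
            out._backward = backward
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def __getitem__(self, key):
        out = self._make(self.data[key], (self,), None)

        def backward(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.add.at(full, key, g)
                self.grad = full if self.grad is None else self.grad + full

        if out.requires_grad:
            out._backward = backward
        return out

    # -- backward pass ----------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._prev:
                visit(p)
            topo.append(t)

        visit(self)
        self._accum(np.asarray(grad, dtype=np.float64))
        for t in reversed(topo):
            if t._backward is not None:
                t._backward(t.grad)


def concat(tensors, axis=-1) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    out = Tensor(data)
    out.requires_grad = any(t.requires_grad for t in tensors)
    if out.requires_grad:
        sizes = [t.data.shape[axis] for t in tensors]
        splits = np.cumsum(sizes)[:-1]
        out._prev = tuple(tensors)

        def backward(g):
            for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
                if t.requires_grad:
                    t._accum(piece)

        out._backward = backward
    return out


def _sparsemax_np(z: np.ndarray) -> np.ndarray:
    """Row-wise Euclidean projection onto the probability simplex."""
    z = np.atleast_2d(z)
    z_sorted = np.sort(z, axis=1)[:, ::-1]
    k = np.arange(1, z.shape[1] + 1)
    cssv = np.cumsum(z_sorted, axis=1)
    cond = 1 + k * z_sorted > cssv
    k_z = cond.sum(axis=1)
    tau = (cssv[np.arange(z.shape[0]), k_z - 1] - 1) / k_z
    return np.maximum(z - tau[:, None], 0.0)


def sparsemax_t(z: Tensor) -> Tensor:
    """Sparsemax with its exact Jacobian-vector product.

    For output rows ``p`` with support S, the backward map is
    ``g_i - mean_{j in S} g_j`` on S and zero elsewhere.
    """
    squeeze = z.data.ndim == 1
    p = _sparsemax_np(z.data)
    out = Tensor(p if not squeeze else p[0])
    out.requires_grad = z.requires_grad
    if z.requires_grad:
        out._prev = (z,)
        support = p > 0

        def backward(g):
            g2 = np.atleast_2d(g)
            ns = support.sum(axis=1, keepdims=True)
            mean_s = (g2 * support).sum(axis=1, keepdims=True) / np.maximum(ns, 1)
            gz = np.where(support, g2 - mean_s, 0.0)
            z._accum(gz if not squeeze else gz[0])

        out._backward = backward
    return out


def bce_with_logits(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Mean binary cross-entropy from raw logits (numerically stable)."""
    z = logits.data
    y = np.asarray(targets, dtype=np.float64).reshape(z.shape)
    loss = np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z)))
    out = Tensor(loss.mean())
    out.requires_grad = logits.requires_grad
    if out.requires_grad:
        out._prev = (logits,)
        s = 1.0 / (1.0 + np.exp(-np.clip(z, -60, 60)))

        def backward(g):
            logits._accum(g * (s - y) / y.size)

        out._backward = backward
    return out


def softmax_cross_entropy(logits: Tensor, onehot: np.ndarray) -> Tensor:
    """Mean cross-entropy between softmax(logits) rows and one-hot targets."""
    z = logits.data
    zmax = z.max(axis=-1, keepdims=True)
    lse = zmax + np.log(np.exp(z - zmax).sum(axis=-1, keepdims=True))
    y = np.asarray(onehot, dtype=np.float64)
    n_rows = int(np.prod(z.shape[:-1]))
    out = Tensor(((lse - z) * y).sum() / n_rows)
    out.requires_grad = logits.requires_grad
    if out.requires_grad:
        out._prev = (logits,)
        p = np.exp(z - lse)

        def backward(g):
            logits._accum(g * (p - y) / n_rows)

        out._backward = backward
    return out
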