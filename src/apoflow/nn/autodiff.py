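"""Minimal reverse-mode automatic differentiation on NumPy arrays.

A :class:`Tensor` wraps a float64 ndarray and records the operation that
produced it; :meth:`Tensor.backward` runs reverse-mode accumulation over
the implicit tape. The op set is exactly what the geometric network and
its training losses need: arithmetic with broadcasting, matmul, reductions,
elementwise nonlinearities, row gather / segment-sum scatter, concatenation
and safe vector norms. Everything is float64; gradients are exact to
machine precision (verified against finite differences in the test suite).
"""

from __future__ import annotations

import numpy as np


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum leading dims
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = requires_grad
        self._parents: tuple = ()
        self._backward = None

    # -- construction helpers ------------------------------------------------
    @staticmethod
    def _wrap(other):
        return other if isinstance(other, Tensor) else Tensor(other)

    @classmethod
    def _from_op(cls, data, parents, backward):
        out = cls(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    # -- arithmetic ----------------------------------------------------------
    def __add__(self, other):
        other = self._wrap(other)

        def backward(g):
            return (_unbroadcast(g, self.shape), _unbroadcast(g, other.shape))

        return Tensor._from_op(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        return Tensor._from_op(-self.data, (self,), lambda g: (-g,))

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)

        def backward(g):
            return (
                _unbroadcast(g * other.data, self.shape),
                _unbroadcast(g * self.data, other.shape),
            )

        return Tensor._from_op(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._wrap(other)

        def backward(g):
            return (
                _unbroadcast(g / other.data, self.shape),
                _unbroadcast(-g * self.data / other.data**2, other.shape),
            )

        return Tensor._from_op(self.data / other.data, (self, other), backward)

    def __rtruediv__(self, other):
        return self._wrap(other) / self

    def __matmul__(self, other):
        other = self._wrap(other)

        def backward(g):
            return (g @ other.data.T, self.data.T @ g)

        return Tensor._from_op(self.data @ other.data, (self, other), backward)

    def square(self):
        return self * self

    def sqrt(self):
        out_data = np.sqrt(self.data)

        def backward(g):
            return (g * 0.5 / out_data,)

        return Tensor._from_op(out_data, (self,), backward)

    def exp(self):
        out_data = np.exp(self.data)
        return Tensor._from_op(out_data, (self,), lambda g: (g * out_data,))

    def tanh(self):
        out_data = np.tanh(self.data)
        return Tensor._from_op(
            out_data, (self,), lambda g: (g * (1.0 - out_data**2),)
        )

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))
        return Tensor._from_op(
            out_data, (self,), lambda g: (g * out_data * (1.0 - out_data),)
        )

    def silu(self):
        s = 1.0 / (1.0 + np.exp(-self.data))
        out_data = self.data * s

        def backward(g):
            return (g * (s + self.data * s * (1.0 - s)),)

        return Tensor._from_op(out_data, (self,), backward)

    def relu(self):
        mask = self.data > 0
        return Tensor._from_op(
            np.where(mask, self.data, 0.0), (self,), lambda g: (g * mask,)
        )

    # -- reductions ----------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            return (np.broadcast_to(g, self.shape).copy(),)

        return Tensor._from_op(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) / float(n)

    # -- structure -----------------------------------------------------------
    def take_rows(self, index: np.ndarray):
        """Gather rows: ``out[k] = self[index[k]]``."""
        index = np.asarray(index, dtype=int)

        def backward(g):
            out = np.zeros_like(self.data)
            np.add.at(out, index, g)
            return (out,)

        return Tensor._from_op(self.data[index], (self,), backward)

    def segment_sum(self, segment_ids: np.ndarray, num_segments: int):
        """Scatter-add rows into ``num_segments`` buckets."""
        segment_ids = np.asarray(segment_ids, dtype=int)
        out_data = np.zeros((num_segments,) + self.data.shape[1:])
        np.add.at(out_data, segment_ids, self.data)

        def backward(g):
            return (g[segment_ids],)

        return Tensor._from_op(out_data, (self,), backward)

    def reshape(self, *shape):
        old = self.shape
        return Tensor._from_op(
            self.data.reshape(*shape), (self,), lambda g: (g.reshape(old),)
        )

    def norm(self, axis=-1, keepdims: bool = True, eps: float = 1e-12):
        """Euclidean norm along ``axis``, smoothed so the gradient is finite
        at zero: ``sqrt(sum(x^2) + eps)``."""
        sq = (self * self).sum(axis=axis, keepdims=keepdims)
        return (sq + eps).sqrt()

    # -- graph traversal -----------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen = set()
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
        self.grad = np.asarray(grad, dtype=np.float64)
        for node in reversed(topo):
            if node._backward is None or node.grad is None:
                continue
            for parent, pg in zip(node._parents, node._backward(node.grad)):
                if not parent.requires_grad:
                    continue
                if parent.grad is None:
                    parent.grad = pg.copy() if isinstance(pg, np.ndarray) else np.asarray(pg, dtype=float)
                else:
                    parent.grad = parent.grad + pg


def concat(tensors, axis: int = -1) -> Tensor:
    """Concatenate tensors along ``axis``."""
    tensors = [Tensor._wrap(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor._from_op(
        np.concatenate([t.data for t in tensors], axis=axis), tensors, backward
    )


def parameter(data, rng=None, scale=None) -> Tensor:
    """A trainable tensor. With ``rng``/``scale``, Glorot-style init."""
    if rng is not None:
        shape = data  # data is a shape tuple in this mode
        if scale is None:
            fan_in = shape[0] if len(shape) > 1 else shape[0]
            scale = 1.0 / np.sqrt(max(fan_in, 1))
        data = rng.standard_normal(shape) * scale
    return Tensor(np.asarray(data, dtype=np.float64), requires_grad=True)


class Adam:
    """Adam optimizer over a dict of named parameter Tensors."""

    def __init__(self, params: dict, lr: float = 1e-3, betas=(0.9, 0.999),
                 eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def step(self):
        self.t += 1
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for p in self.params.values():
            p.grad = None
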