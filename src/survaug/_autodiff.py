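"""Minimal reverse-mode automatic differentiation over numpy arrays.

All model training in this package (VAEs, the latent discriminator, the
discrete-time survival head) runs on this tape.  Arrays are float64
throughout; at the matrix sizes this package targets (hundreds of features,
thousands of samples) that is fast enough on one CPU and keeps training
bit-reproducible.

Only the operations the models need are implemented: affine maps, the
elementwise nonlinearities, sums/means, and clipping for safe logs.
Gradient correctness is enforced by finite-difference property tests.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "constant", "relu", "sigmoid", "exp", "log", "clip",
           "matmul", "tsum", "tmean"]


class Tensor:
    """A numpy array plus the tape bookkeeping needed for backprop."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_grad_fns")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad)
        self.grad = None
        self._parents: tuple = ()
        self._grad_fns: tuple = ()

    # -- introspection -----------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def __repr__(self):  # pragma: no cover
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- graph construction ------------------------------------------------
    @staticmethod
    def _make(data, parents, grad_fns):
        needs = any(p.requires_grad or p._parents for p in parents)
        out = Tensor(data)
        if needs:
            out.requires_grad = True
            out._parents = tuple(parents)
            out._grad_fns = tuple(grad_fns)
        return out

    # -- arithmetic --------------------------------------------------------
    def __add__(self, other):
        other = _as_tensor(other)
        return Tensor._make(
            self.data + other.data,
            (self, other),
            (lambda g: _unbroadcast(g, self.data.shape),
             lambda g: _unbroadcast(g, other.data.shape)),
        )

    __radd__ = __add__

    def __sub__(self, other):
        other = _as_tensor(other)
        return Tensor._make(
            self.data - other.data,
            (self, other),
            (lambda g: _unbroadcast(g, self.data.shape),
             lambda g: _unbroadcast(-g, other.data.shape)),
        )

    def __rsub__(self, other):
        return _as_tensor(other) - self

    def __mul__(self, other):
        other = _as_tensor(other)
        return Tensor._make(
            self.data * other.data,
            (self, other),
            (lambda g: _unbroadcast(g * other.data, self.data.shape),
             lambda g: _unbroadcast(g * self.data, other.data.shape)),
        )

    __rmul__ = __mul__

    def __neg__(self):
        return Tensor._make(-self.data, (self,), (lambda g: -g,))

    def __truediv__(self, other):
        if isinstance(other, Tensor):
            raise TypeError("division by a Tensor is not supported; multiply by a reciprocal")
        return self * (1.0 / float(other))

    def __matmul__(self, other):
        return matmul(self, other)

    def __pow__(self, p):
        if p != 2:
            raise ValueError("only squaring is supported")
        return self * self

    # -- backward ----------------------------------------------------------
    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        order: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative topological sort; deep graphs must not recurse
            node, processed = stack.pop()
            if processed:
                order.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(order):
            if node.grad is None:
                continue
            for parent, fn in zip(node._parents, node._grad_fns):
                g = fn(node.grad)
                parent.grad = g if parent.grad is None else parent.grad + g


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def constant(x) -> Tensor:
    """Wrap an array as a constant (no-gradient) node."""
    return Tensor(np.asarray(x, dtype=np.float64))


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum a gradient back down to the shape it was broadcast from."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, s in enumerate(shape):
        if s == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


def matmul(a: Tensor, b: Tensor) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    return Tensor._make(
        a.data @ b.data,
        (a, b),
        (lambda g: g @ b.data.T, lambda g: a.data.T @ g),
    )


def relu(x: Tensor) -> Tensor:
    x = _as_tensor(x)
    mask = x.data > 0
    return Tensor._make(x.data * mask, (x,), (lambda g: g * mask,))


def sigmoid(x: Tensor) -> Tensor:
    x = _as_tensor(x)
    out = np.empty_like(x.data)
    pos = x.data >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x.data[pos]))
    e = np.exp(x.data[~pos])
    out[~pos] = e / (1.0 + e)
    return Tensor._make(out, (x,), (lambda g: g * out * (1.0 - out),))


def exp(x: Tensor) -> Tensor:
    x = _as_tensor(x)
    out = np.exp(x.data)
    return Tensor._make(out, (x,), (lambda g: g * out,))


def log(x: Tensor) -> Tensor:
    x = _as_tensor(x)
    return Tensor._make(np.log(x.data), (x,), (lambda g: g / x.data,))


def clip(x: Tensor, lo: float, hi: float) -> Tensor:
    """Clip values; gradient passes only through the interior."""
    x = _as_tensor(x)
    mask = (x.data > lo) & (x.data < hi)
    return Tensor._make(np.clip(x.data, lo, hi), (x,), (lambda g: g * mask,))


def tsum(x: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    x = _as_tensor(x)
    out = x.data.sum(axis=axis, keepdims=keepdims)

    def grad_fn(g):
        if axis is None:
            return np.broadcast_to(g, x.data.shape).copy()
        gg = g if keepdims else np.expand_dims(g, axis)
        return np.broadcast_to(gg, x.data.shape).copy()

    return Tensor._make(out, (x,), (grad_fn,))


def tmean(x: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    x = _as_tensor(x)
    n = x.data.size if axis is None else x.data.shape[axis]
    return tsum(x, axis=axis, keepdims=keepdims) * (1.0 / n)
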