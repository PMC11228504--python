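"""Minimal reverse-mode automatic differentiation on numpy arrays.

The matching pipeline needs gradients of a masked-token loss with respect
to the per-species parameterization matrices, flowing through the Sinkhorn
relaxation and through convex row mixtures of one-hot sequence encodings.
The graphs involved are small (a few hundred nodes per gradient step), so a
light tape over numpy is sufficient: each :class:`Var` records its parents
and vector-Jacobian products, and :func:`backward` walks the tape in
reverse topological order.

Only the operations the pipeline uses are provided; all of them support the
shapes that actually occur (2-D matrices, 3-D one-hot stacks, gathered
vectors) and broadcasting where noted.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Var",
    "asvar",
    "backward",
    "matmul",
    "exp",
    "log",
    "logsumexp",
    "vsum",
    "index",
    "mix_rows",
    "straight_through",
]


class Var:
    """A node in the tape: an ndarray value plus backward closures."""

    __slots__ = ("data", "grad", "_parents", "_vjps")

    def __init__(self, data, parents=(), vjps=()):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self._parents = tuple(parents)
        self._vjps = tuple(vjps)

    @property
    def shape(self):
        return self.data.shape

    # -- operator sugar ----------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    def __radd__(self, other):
        return add(self, other)

    def __sub__(self, other):
        return add(self, neg(asvar(other)))

    def __rsub__(self, other):
        return add(neg(self), other)

    def __mul__(self, other):
        return mul(self, other)

    def __rmul__(self, other):
        return mul(self, other)

    def __truediv__(self, other):
        if isinstance(other, Var):
            raise TypeError("division only supported by constants")
        return mul(self, 1.0 / np.asarray(other, dtype=np.float64))

    def __neg__(self):
        return neg(self)

    def __repr__(self):  # pragma: no cover - debug aid
        return f"Var(shape={self.data.shape}, leaf={not self._parents})"


def asvar(x) -> Var:
    """Wrap a constant as a leaf Var (no parents, gradient discarded)."""
    return x if isinstance(x, Var) else Var(x)


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (reverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


def add(a, b) -> Var:
    a, b = asvar(a), asvar(b)
    out = a.data + b.data
    return Var(
        out,
        parents=(a, b),
        vjps=(
            lambda g, a=a: _unbroadcast(g, a.data.shape),
            lambda g, b=b: _unbroadcast(g, b.data.shape),
        ),
    )


def neg(a) -> Var:
    a = asvar(a)
    return Var(-a.data, parents=(a,), vjps=(lambda g: -g,))


def mul(a, b) -> Var:
    a, b = asvar(a), asvar(b)
    out = a.data * b.data
    return Var(
        out,
        parents=(a, b),
        vjps=(
            lambda g, a=a, b=b: _unbroadcast(g * b.data, a.data.shape),
            lambda g, a=a, b=b: _unbroadcast(g * a.data, b.data.shape),
        ),
    )


def matmul(a, b) -> Var:
    """2-D matrix product."""
    a, b = asvar(a), asvar(b)
    out = a.data @ b.data
    return Var(
        out,
        parents=(a, b),
        vjps=(
            lambda g, b=b: g @ b.data.T,
            lambda g, a=a: a.data.T @ g,
        ),
    )


def exp(a) -> Var:
    a = asvar(a)
    out = np.exp(a.data)
    return Var(out, parents=(a,), vjps=(lambda g, out=out: g * out,))


def log(a) -> Var:
    a = asvar(a)
    return Var(np.log(a.data), parents=(a,), vjps=(lambda g, a=a: g / a.data,))


def logsumexp(a, axis: int, keepdims: bool = True) -> Var:
    """Stable log-sum-exp along one axis; softmax as the backward weights."""
    a = asvar(a)
    amax = np.max(a.data, axis=axis, keepdims=True)
    shifted = np.exp(a.data - amax)
    total = shifted.sum(axis=axis, keepdims=True)
    out = np.log(total) + amax
    softmax = shifted / total

    def vjp(g, softmax=softmax, axis=axis, keepdims=keepdims):
        if not keepdims:
            g = np.expand_dims(g, axis)
        return g * softmax

    if not keepdims:
        out = np.squeeze(out, axis=axis)
    return Var(out, parents=(a,), vjps=(vjp,))


def vsum(a, axis=None) -> Var:
    a = asvar(a)
    out = a.data.sum(axis=axis)

    def vjp(g, a=a, axis=axis):
        if axis is None:
            return np.broadcast_to(g, a.data.shape).copy()
        g = np.expand_dims(g, axis)
        return np.broadcast_to(g, a.data.shape).copy()

    return Var(out, parents=(a,), vjps=(vjp,))


def index(a, key) -> Var:
    """Differentiable indexing.

    `key` may be a basic slice or a tuple of integer arrays (fancy
    indexing); trailing dimensions are kept.  The backward pass scatter-adds
    into the parent, so repeated indices accumulate correctly.
    """
    a = asvar(a)
    out = a.data[key]
    fancy = isinstance(key, tuple) and any(isinstance(k, np.ndarray) for k in key)
    fancy = fancy or isinstance(key, np.ndarray)

    def vjp(g, a=a, key=key, fancy=fancy):
        full = np.zeros_like(a.data)
        if fancy:
            np.add.at(full, key, g)
        else:
            full[key] += g
        return full

    return Var(out, parents=(a,), vjps=(vjp,))


def mix_rows(weights, onehot: np.ndarray) -> Var:
    """Convex mixture of one-hot row stacks: (n, n) x (n, L, q) -> (n, L, q).

    Row i of the output is sum_j weights[i, j] * onehot[j]; this is how a
    (soft) permutation acts on the encoded rows of one alignment.
    """
    weights = asvar(weights)
    onehot = np.asarray(onehot, dtype=np.float64)
    out = np.tensordot(weights.data, onehot, axes=(1, 0))

    def vjp(g, onehot=onehot):
        return np.tensordot(g, onehot, axes=([1, 2], [1, 2]))

    return Var(out, parents=(weights,), vjps=(vjp,))


def straight_through(soft: Var, hard: np.ndarray) -> Var:
    """Forward the hard value; pass gradients through to the soft one."""
    hard = np.asarray(hard, dtype=np.float64)
    if hard.shape != soft.data.shape:
        raise ValueError("hard/soft shape mismatch")
    return Var(hard, parents=(soft,), vjps=(lambda g: g,))


def backward(out: Var) -> None:
    """Accumulate gradients of `out` (a scalar) into every tape leaf."""
    if out.data.size != 1:
        raise ValueError("backward() expects a scalar output")
    order: list[Var] = []
    seen: set[int] = set()
    stack: list[tuple[Var, bool]] = [(out, False)]
    while stack:
        node, processed = stack.pop()
        if processed:
            order.append(node)
            continue
        if id(node) in seen:
            continue
        seen.add(id(node))
        stack.append((node, True))
        for parent in node._parents:
            if id(parent) not in seen:
                stack.append((parent, False))
    out.grad = np.ones_like(out.data)
    for node in reversed(order):
        if node.grad is None:
            continue
        for parent, vjp in zip(node._parents, node._vjps):
            contribution = vjp(node.grad)
            if parent.grad is None:
                parent.grad = np.zeros_like(parent.data)
            parent.grad += contribution
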