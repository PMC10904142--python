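"""Minimal reverse-mode automatic differentiation on NumPy arrays.

The network in this package needs gradients of scalar losses with respect to
weight matrices flowing through a fixed, fairly small vocabulary of array
operations: affine maps, channel-wise linear maps on stacks of 3-vectors,
concatenation, row gather/segment-mean (message passing), guarded vector
norms, pointwise nonlinearities and the two losses.  This module implements
exactly that vocabulary as a tape-based reverse-mode engine.

Everything is double precision.  A :class:`Tensor` wraps an ``ndarray``; each
operation records, per parent, a closure mapping the output cotangent to the
parent's cotangent contribution.  ``Tensor.backward()`` topologically sorts
the tape and accumulates gradients.  All gradients are checked against central
finite differences in the test-suite.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit

__all__ = [
    "Tensor",
    "astensor",
    "concat",
    "gather_rows",
    "scatter_mean",
    "channel_map",
    "vec_norm",
    "silu",
    "sigmoid",
    "relu",
    "softmax_cross_entropy",
    "mse",
    "ACTIVATIONS",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` over the axes that broadcasting expanded to reach ``shape``."""
    if grad.shape == shape:
        return grad
    # sum leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    """An ``ndarray`` with an optional gradient tape behind it."""

    __slots__ = ("data", "grad", "parents", "requires_grad")

    def __init__(self, data, requires_grad: bool = False, parents=()):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad) or any(
            p.requires_grad for p, _ in parents
        )
        self.parents = tuple(parents) if self.requires_grad else ()
        self.grad: np.ndarray | None = None

    # -- plumbing ---------------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient needs a scalar output")
            grad = np.ones_like(self.data)
        # topological order over the tape
        order: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, expanded = stack.pop()
            if expanded:
                order.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for parent, _ in node.parents:
                stack.append((parent, False))
        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=np.float64)}
        for node in reversed(order):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if not node.parents:
                node.grad = g if node.grad is None else node.grad + g
                continue
            for parent, fn in node.parents:
                if not parent.requires_grad:
                    continue
                contrib = fn(g)
                key = id(parent)
                if key in grads:
                    grads[key] = grads[key] + contrib
                else:
                    grads[key] = contrib

    # -- arithmetic -------------------------------------------------------

    def __add__(self, other):
        other = astensor(other)
        return Tensor(
            self.data + other.data,
            parents=(
                (self, lambda g: _unbroadcast(g, self.data.shape)),
                (other, lambda g: _unbroadcast(g, other.data.shape)),
            ),
        )

    __radd__ = __add__

    def __neg__(self):
        return Tensor(-self.data, parents=((self, lambda g: -g),))

    def __sub__(self, other):
        return self + (-astensor(other))

    def __rsub__(self, other):
        return astensor(other) + (-self)

    def __mul__(self, other):
        other = astensor(other)
        return Tensor(
            self.data * other.data,
            parents=(
                (self, lambda g: _unbroadcast(g * other.data, self.data.shape)),
                (other, lambda g: _unbroadcast(g * self.data, other.data.shape)),
            ),
        )

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = astensor(other)
        return Tensor(
            self.data / other.data,
            parents=(
                (self, lambda g: _unbroadcast(g / other.data, self.data.shape)),
                (
                    other,
                    lambda g: _unbroadcast(
                        -g * self.data / other.data**2, other.data.shape
                    ),
                ),
            ),
        )

    def __pow__(self, exponent: float):
        out = self.data**exponent
        return Tensor(
            out,
            parents=((self, lambda g: g * exponent * self.data ** (exponent - 1)),),
        )

    def __matmul__(self, other):
        other = astensor(other)
        return Tensor(
            self.data @ other.data,
            parents=(
                (self, lambda g: g @ other.data.swapaxes(-1, -2)),
                (other, lambda g: self.data.swapaxes(-1, -2) @ g),
            ),
        )

    # -- reductions / reshaping ------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        out = self.data.sum(axis=axis, keepdims=keepdims)

        def grad_fn(g):
            if axis is None:
                return np.broadcast_to(g, self.data.shape).copy()
            gg = g if keepdims else np.expand_dims(g, axis)
            return np.broadcast_to(gg, self.data.shape).copy()

        return Tensor(out, parents=((self, grad_fn),))

    def mean(self, axis=None, keepdims: bool = False):
        count = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / count)

    def reshape(self, *shape):
        orig = self.data.shape
        return Tensor(
            self.data.reshape(*shape), parents=((self, lambda g: g.reshape(orig)),)
        )

    def exp(self):
        out = np.exp(self.data)
        return Tensor(out, parents=((self, lambda g: g * out),))

    def sqrt(self):
        out = np.sqrt(self.data)
        return Tensor(out, parents=((self, lambda g: g * 0.5 / out),))


def astensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


# -- structural ops -------------------------------------------------------


def concat(tensors, axis: int = -1) -> Tensor:
    tensors = [astensor(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def make_fn(i):
        lo, hi = offsets[i], offsets[i + 1]

        def fn(g):
            index = [slice(None)] * g.ndim
            index[axis] = slice(lo, hi)
            return g[tuple(index)]

        return fn

    return Tensor(data, parents=tuple((t, make_fn(i)) for i, t in enumerate(tensors)))


def gather_rows(x: Tensor, index: np.ndarray) -> Tensor:
    """Select rows ``x[index]`` along the first axis (message-passing gather)."""
    x = astensor(x)
    index = np.asarray(index, dtype=np.intp)

    def grad_fn(g):
        out = np.zeros_like(x.data)
        np.add.at(out, index, g)
        return out

    return Tensor(x.data[index], parents=((x, grad_fn),))


def scatter_mean(src: Tensor, index: np.ndarray, num_segments: int) -> Tensor:
    """Segment mean over the first axis; empty segments yield zero rows."""
    src = astensor(src)
    index = np.asarray(index, dtype=np.intp)
    counts = np.bincount(index, minlength=num_segments).astype(np.float64)
    safe = np.maximum(counts, 1.0)
    scale = (1.0 / safe).reshape((num_segments,) + (1,) * (src.ndim - 1))
    acc = np.zeros((num_segments,) + src.data.shape[1:], dtype=np.float64)
    np.add.at(acc, index, src.data)
    out = acc * scale

    def grad_fn(g):
        return (g * scale)[index]

    return Tensor(out, parents=((src, grad_fn),))


def channel_map(v: Tensor, w: Tensor) -> Tensor:
    """Linear map on the channel axis of a stack of 3-vectors.

    ``v`` has shape (rows, r, 3) and ``w`` shape (r, r'); the output is
    ``einsum('nrc,rk->nkc')``.  The three Cartesian components are never
    mixed, which is what makes every such map SO(3)-equivariant.
    """
    v, w = astensor(v), astensor(w)
    out = np.einsum("nrc,rk->nkc", v.data, w.data, optimize=True)
    return Tensor(
        out,
        parents=(
            (v, lambda g: np.einsum("nkc,rk->nrc", g, w.data, optimize=True)),
            (w, lambda g: np.einsum("nrc,nkc->rk", v.data, g, optimize=True)),
        ),
    )


def vec_norm(v: Tensor, eps: float = 1e-8) -> Tensor:
    """Per-channel guarded L2 norm over the Cartesian axis: (rows, r, 3) -> (rows, r)."""
    v = astensor(v)
    sq = np.sum(v.data**2, axis=-1)
    out = np.sqrt(sq + eps**2)

    def grad_fn(g):
        return v.data * (g / out)[..., None]

    return Tensor(out, parents=((v, grad_fn),))


# -- nonlinearities -------------------------------------------------------


def sigmoid(x: Tensor) -> Tensor:
    x = astensor(x)
    out = expit(x.data)
    return Tensor(out, parents=((x, lambda g: g * out * (1.0 - out)),))


def silu(x: Tensor) -> Tensor:
    x = astensor(x)
    sig = expit(x.data)
    out = x.data * sig

    def grad_fn(g):
        return g * (sig + x.data * sig * (1.0 - sig))

    return Tensor(out, parents=((x, grad_fn),))


def relu(x: Tensor) -> Tensor:
    x = astensor(x)
    mask = x.data > 0
    return Tensor(x.data * mask, parents=((x, lambda g: g * mask),))


def identity(x: Tensor) -> Tensor:
    return astensor(x)


ACTIVATIONS = {
    "silu": silu,
    "sigmoid": sigmoid,
    "relu": relu,
    "identity": identity,
}


# -- losses ---------------------------------------------------------------


def softmax_cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean cross-entropy of integer ``labels`` under row-wise softmax of ``logits``."""
    logits = astensor(logits)
    labels = np.asarray(labels, dtype=np.intp)
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    expz = np.exp(z)
    probs = expz / expz.sum(axis=1, keepdims=True)
    n = logits.data.shape[0]
    loss = -np.mean(np.log(probs[np.arange(n), labels] + 1e-300))

    def grad_fn(g):
        d = probs.copy()
        d[np.arange(n), labels] -= 1.0
        return g * d / n

    return Tensor(loss, parents=((logits, grad_fn),))


def mse(pred: Tensor, target) -> Tensor:
    """Mean squared error over all elements."""
    pred = astensor(pred)
    diff = pred - astensor(target)
    return (diff * diff).mean()
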