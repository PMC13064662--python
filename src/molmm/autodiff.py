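"""Minimal reverse-mode automatic differentiation over numpy arrays.

The engine exists for one reason: bilevel (meta) training needs gradients
of functions that are themselves built from gradients.  Every backward
rule below therefore emits ordinary graph operations, so ``grad`` applied
to the output of ``grad`` is exact (double backward), with no special
casing.  Only the primitives the network layers require are provided.

All data is float64; shapes follow numpy broadcasting for ``+`` and ``*``.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "tensor", "grad"]


class Tensor:
    """A node in the computation graph wrapping a float64 ndarray."""

    __slots__ = ("data", "parents", "backward_fn")

    def __init__(self, data, parents=(), backward_fn=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.parents = parents
        self.backward_fn = backward_fn

    @property
    def shape(self):
        return self.data.shape

    @property
    def size(self):
        return self.data.size

    # -- operator sugar ------------------------------------------------
    def __add__(self, other):
        return add(self, _wrap(other))

    def __radd__(self, other):
        return add(_wrap(other), self)

    def __sub__(self, other):
        return add(self, neg(_wrap(other)))

    def __rsub__(self, other):
        return add(_wrap(other), neg(self))

    def __mul__(self, other):
        return mul(self, _wrap(other))

    def __rmul__(self, other):
        return mul(_wrap(other), self)

    def __truediv__(self, other):
        return mul(self, reciprocal(_wrap(other)))

    def __neg__(self):
        return neg(self)

    def __matmul__(self, other):
        return matmul(self, _wrap(other))

    def __repr__(self):  # pragma: no cover
        return f"Tensor(shape={self.data.shape}, leaf={self.backward_fn is None})"


def tensor(data):
    """Create a leaf tensor."""
    return Tensor(data)


def _wrap(x):
    return x if isinstance(x, Tensor) else Tensor(x)


# ---------------------------------------------------------------------
# primitives
# ---------------------------------------------------------------------

def _sum_to(t: Tensor, shape) -> Tensor:
    """Reduce ``t`` back to ``shape`` after numpy broadcasting (graph op)."""
    if t.data.shape == tuple(shape):
        return t
    # remove extra leading axes
    extra = t.data.ndim - len(shape)
    if extra > 0:
        t = tsum(t, axis=tuple(range(extra)))
    axes = tuple(i for i, n in enumerate(shape) if n == 1 and t.data.shape[i] != 1)
    if axes:
        t = tsum(t, axis=axes, keepdims=True)
    return reshape(t, shape)


def add(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.data + b.data, (a, b))
    out.backward_fn = lambda g: (_sum_to(g, a.shape), _sum_to(g, b.shape))
    return out


def neg(a: Tensor) -> Tensor:
    out = Tensor(-a.data, (a,))
    out.backward_fn = lambda g: (neg(g),)
    return out


def mul(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.data * b.data, (a, b))
    out.backward_fn = lambda g: (_sum_to(mul(g, b), a.shape), _sum_to(mul(g, a), b.shape))
    return out


def reciprocal(a: Tensor) -> Tensor:
    out = Tensor(1.0 / a.data, (a,))
    out.backward_fn = lambda g: (neg(mul(g, mul(out, out))),)
    return out


def matmul(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.data @ b.data, (a, b))
    out.backward_fn = lambda g: (matmul(g, transpose(b)), matmul(transpose(a), g))
    return out


def transpose(a: Tensor) -> Tensor:
    out = Tensor(a.data.T, (a,))
    out.backward_fn = lambda g: (transpose(g),)
    return out


def permute(a: Tensor, axes) -> Tensor:
    axes = tuple(axes)
    inv = tuple(np.argsort(axes))
    out = Tensor(np.transpose(a.data, axes), (a,))
    out.backward_fn = lambda g: (permute(g, inv),)
    return out


def reshape(a: Tensor, shape) -> Tensor:
    shape = tuple(shape)
    orig = a.data.shape
    out = Tensor(a.data.reshape(shape), (a,))
    out.backward_fn = lambda g: (reshape(g, orig),)
    return out


def broadcast_to(a: Tensor, shape) -> Tensor:
    shape = tuple(shape)
    orig = a.data.shape
    out = Tensor(np.broadcast_to(a.data, shape).copy(), (a,))
    out.backward_fn = lambda g: (_sum_to(g, orig),)
    return out


def tsum(a: Tensor, axis=None, keepdims=False) -> Tensor:
    orig = a.data.shape
    out = Tensor(a.data.sum(axis=axis, keepdims=keepdims), (a,))

    def backward(g):
        gd = g
        if axis is not None and not keepdims:
            kshape = list(orig)
            axes = (axis,) if isinstance(axis, int) else axis
            for ax in axes:
                kshape[ax] = 1
            gd = reshape(gd, kshape)
        elif axis is None and not keepdims:
            gd = reshape(gd, (1,) * len(orig))
        return (broadcast_to(gd, orig),)

    out.backward_fn = backward
    return out


def tmean(a: Tensor, axis=None, keepdims=False) -> Tensor:
    n = a.data.size if axis is None else np.prod(
        [a.data.shape[ax] for ax in ((axis,) if isinstance(axis, int) else axis)]
    )
    return tsum(a, axis=axis, keepdims=keepdims) * (1.0 / float(n))


def relu(a: Tensor) -> Tensor:
    mask = Tensor((a.data > 0).astype(np.float64))
    out = Tensor(a.data * mask.data, (a,))
    out.backward_fn = lambda g: (mul(g, mask),)
    return out


def tanh(a: Tensor) -> Tensor:
    out = Tensor(np.tanh(a.data), (a,))
    out.backward_fn = lambda g: (mul(g, 1.0 - mul(out, out)),)
    return out


def sigmoid(a: Tensor) -> Tensor:
    # numerically stable logistic
    x = a.data
    s = np.where(x >= 0, 1.0 / (1.0 + np.exp(-np.abs(x))),
                 np.exp(-np.abs(x)) / (1.0 + np.exp(-np.abs(x))))
    out = Tensor(s, (a,))
    out.backward_fn = lambda g: (mul(g, mul(out, 1.0 - out)),)
    return out


def exp(a: Tensor) -> Tensor:
    out = Tensor(np.exp(a.data), (a,))
    out.backward_fn = lambda g: (mul(g, out),)
    return out


def log(a: Tensor) -> Tensor:
    out = Tensor(np.log(a.data), (a,))
    out.backward_fn = lambda g: (mul(g, reciprocal(a)),)
    return out


def softplus(a: Tensor) -> Tensor:
    out = Tensor(np.logaddexp(0.0, a.data), (a,))
    out.backward_fn = lambda g: (mul(g, sigmoid(a)),)
    return out


def take(a: Tensor, idx: np.ndarray) -> Tensor:
    """Gather from the flattened tensor; backward is scatter-add."""
    idx = np.asarray(idx)
    orig = a.data.shape
    out = Tensor(a.data.reshape(-1)[idx], (a,))
    out.backward_fn = lambda g: (scatter_add(g, idx, orig),)
    return out


def scatter_add(g: Tensor, idx: np.ndarray, shape) -> Tensor:
    """Scatter-add ``g`` at flat indices ``idx`` into zeros of ``shape``."""
    shape = tuple(shape)
    flat = np.zeros(int(np.prod(shape)))
    np.add.at(flat, idx.reshape(-1), g.data.reshape(-1))
    out = Tensor(flat.reshape(shape), (g,))
    out.backward_fn = lambda up: (reshape(take(up, idx.reshape(-1)), g.data.shape),)
    return out


# ---------------------------------------------------------------------
# differentiation
# ---------------------------------------------------------------------

def _topo(output: Tensor):
    order, seen, stack = [], set(), [(output, False)]
    while stack:
        node, done = stack.pop()
        if done:
            order.append(node)
            continue
        if id(node) in seen:
            continue
        seen.add(id(node))
        stack.append((node, True))
        for p in node.parents:
            stack.append((p, False))
    return order


def grad(output: Tensor, inputs, grad_output: Tensor | None = None):
    """Gradients of a scalar (or seeded) output with respect to ``inputs``.

    The returned gradients are themselves graph tensors, so they can be
    differentiated again (full double backward).
    """
    inputs = list(inputs)
    if grad_output is None:
        if output.data.size != 1:
            raise ValueError("grad of a non-scalar requires grad_output")
        grad_output = Tensor(np.ones_like(output.data))
    grads: dict[int, Tensor] = {id(output): grad_output}
    for node in reversed(_topo(output)):
        g = grads.get(id(node))
        if g is None or node.backward_fn is None:
            continue
        for parent, pg in zip(node.parents, node.backward_fn(g)):
            if pg is None:
                continue
            prev = grads.get(id(parent))
            grads[id(parent)] = pg if prev is None else add(prev, pg)
        # keep graph references alive through dict keyed by id
    out = []
    for inp in inputs:
        out.append(grads.get(id(inp), Tensor(np.zeros_like(inp.data))))
    return out
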