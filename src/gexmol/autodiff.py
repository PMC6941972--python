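"""Minimal reverse-mode automatic differentiation on numpy arrays.

The engine supports the two things the package actually needs:

* first-order gradients of scalar losses with respect to network weights
  (translator and GAN training), and
* differentiating *through* a gradient (``create_graph=True``), which the
  WGAN gradient penalty requires: the penalty is a function of
  ``∇_x D(x)`` and must itself be back-propagated into the critic weights.

Every vector-Jacobian product is expressed in terms of :class:`Tensor`
operations, so gradients are ordinary graph nodes and can be differentiated
again.  Shapes follow numpy broadcasting; ``matmul`` is restricted to 2-D
operands, which is all the MLP/GRU stack uses.
"""

from __future__ import annotations

import contextlib
from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = ["Tensor", "as_tensor", "no_grad", "grad", "concat"]

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    """Context manager disabling graph recording (inference / optimizer steps)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


class Tensor:
    """A numpy array plus the recipe for its vector-Jacobian products."""

    __slots__ = ("data", "requires_grad", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad)
        # list of (parent Tensor, vjp: Tensor -> Tensor)
        self._parents: list[tuple["Tensor", Callable]] = []

    # -- construction -----------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- operators --------------------------------------------------------
    def __add__(self, other):
        return _binary(self, other, np.add, _vjp_add_a, _vjp_add_b)

    __radd__ = __add__

    def __sub__(self, other):
        return _binary(self, other, np.subtract, _vjp_add_a, _vjp_sub_b)

    def __rsub__(self, other):
        return as_tensor(other) - self

    def __mul__(self, other):
        return _binary(self, other, np.multiply, _vjp_mul_a, _vjp_mul_b)

    __rmul__ = __mul__

    def __truediv__(self, other):
        return self * as_tensor(other) ** -1.0

    def __rtruediv__(self, other):
        return as_tensor(other) * self ** -1.0

    def __neg__(self):
        return self * -1.0

    def __pow__(self, exponent: float):
        exponent = float(exponent)
        out_data = np.power(self.data, exponent)
        x = self

        def vjp(g):
            return g * (exponent * x ** (exponent - 1.0))

        return _node(out_data, [(x, vjp)])

    def __matmul__(self, other):
        other = as_tensor(other)
        a, b = self, other
        out_data = a.data @ b.data

        def vjp_a(g):
            return g @ b.transpose()

        def vjp_b(g):
            return a.transpose() @ g

        return _node(out_data, [(a, vjp_a), (b, vjp_b)])

    # -- shape ops --------------------------------------------------------
    def transpose(self):
        x = self

        def vjp(g):
            return g.transpose()

        return _node(self.data.T, [(x, vjp)])

    @property
    def T(self):
        return self.transpose()

    def reshape(self, *shape):
        x = self
        old_shape = self.data.shape

        def vjp(g):
            return g.reshape(*old_shape)

        return _node(self.data.reshape(*shape), [(x, vjp)])

    def broadcast_to(self, shape):
        x = self
        old_shape = self.data.shape

        def vjp(g):
            return _unbroadcast(g, old_shape)

        return _node(np.broadcast_to(self.data, shape).copy(), [(x, vjp)])

    # -- reductions -------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        x = self
        in_shape = self.data.shape
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def vjp(g):
            gd = g
            if not keepdims and axis is not None:
                axes = axis if isinstance(axis, tuple) else (axis,)
                shape = list(gd.data.shape)
                for ax in sorted(a % len(in_shape) for a in axes):
                    shape.insert(ax, 1)
                gd = gd.reshape(*shape)
            elif not keepdims and axis is None:
                gd = gd.reshape(*([1] * len(in_shape)))
            return gd.broadcast_to(in_shape)

        return _node(out_data, [(x, vjp)])

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    # -- nonlinearities ---------------------------------------------------
    def tanh(self):
        out = _node(np.tanh(self.data), [])
        x = self

        def vjp(g):
            return g * (1.0 - out * out)

        _attach(out, [(x, vjp)])
        return out

    def sigmoid(self):
        out = _node(1.0 / (1.0 + np.exp(-self.data)), [])
        x = self

        def vjp(g):
            return g * (out * (1.0 - out))

        _attach(out, [(x, vjp)])
        return out

    def exp(self):
        out = _node(np.exp(self.data), [])
        x = self

        def vjp(g):
            return g * out

        _attach(out, [(x, vjp)])
        return out

    def log(self):
        x = self

        def vjp(g):
            return g * x ** -1.0

        return _node(np.log(self.data), [(x, vjp)])

    def leaky_relu(self, slope: float = 0.2):
        scale = np.where(self.data > 0, 1.0, slope)
        x = self
        const = Tensor(scale)

        def vjp(g):
            return g * const

        return _node(self.data * scale, [(x, vjp)])

    def clip(self, lo: float, hi: float):
        """Clamp values; gradient passes only where unclipped."""
        inside = Tensor(((self.data > lo) & (self.data < hi)).astype(np.float64))
        x = self

        def vjp(g):
            return g * inside

        return _node(np.clip(self.data, lo, hi), [(x, vjp)])

    def sqrt(self):
        return self ** 0.5


# ---------------------------------------------------------------------------
# helpers


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _node(data: np.ndarray, parents) -> Tensor:
    t = Tensor(data)
    _attach(t, parents)
    return t


def _attach(t: Tensor, parents) -> None:
    if not _GRAD_ENABLED:
        return
    kept = [(p, f) for p, f in parents if p.requires_grad or p._parents]
    if kept:
        t._parents = kept
        t.requires_grad = True


def _unbroadcast(g: Tensor, shape) -> Tensor:
    """Reduce gradient ``g`` back to ``shape`` after numpy broadcasting."""
    if g.data.shape == tuple(shape):
        return g
    extra = g.data.ndim - len(shape)
    if extra > 0:
        g = g.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.data.shape[i] != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g.reshape(*shape)


def _vjp_add_a(g, a, b):
    return _unbroadcast(g, a.data.shape)


def _vjp_add_b(g, a, b):
    return _unbroadcast(g, b.data.shape)


def _vjp_sub_b(g, a, b):
    return _unbroadcast(-g, b.data.shape)


def _vjp_mul_a(g, a, b):
    return _unbroadcast(g * b, a.data.shape)


def _vjp_mul_b(g, a, b):
    return _unbroadcast(g * a, b.data.shape)


def _binary(a, other, fwd, vjp_a, vjp_b) -> Tensor:
    a = as_tensor(a)
    b = as_tensor(other)
    return _node(
        fwd(a.data, b.data),
        [(a, lambda g: vjp_a(g, a, b)), (b, lambda g: vjp_b(g, a, b))],
    )


def concat(tensors: Sequence[Tensor], axis: int = 1) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    parents = []
    start = 0
    for t in tensors:
        size = t.data.shape[axis]
        sl = [slice(None)] * data.ndim
        sl[axis] = slice(start, start + size)
        parents.append((t, _make_slice_vjp(tuple(sl))))
        start += size
    return _node(data, parents)


def _make_slice_vjp(sl):
    def vjp(g):
        return _slice(g, sl)

    return vjp


def _slice(t: Tensor, sl) -> Tensor:
    x = t
    in_shape = t.data.shape

    def vjp(g):
        # scatter g into the sliced region; the scatter's own vjp is the slice
        return _node(_scatter(g.data, in_shape, sl), [(g, lambda gg: _slice(gg, sl))])

    return _node(t.data[sl].copy(), [(x, vjp)])


def _scatter(gdata: np.ndarray, shape, sl) -> np.ndarray:
    out = np.zeros(shape)
    out[sl] = gdata
    return out


# ---------------------------------------------------------------------------
# backward


def _toposort(root: Tensor) -> list[Tensor]:
    order: list[Tensor] = []
    seen: set[int] = set()
    stack: list[tuple[Tensor, bool]] = [(root, False)]
    while stack:
        node, processed = stack.pop()
        if processed:
            order.append(node)
            continue
        if id(node) in seen:
            continue
        seen.add(id(node))
        stack.append((node, True))
        for parent, _ in node._parents:
            if id(parent) not in seen:
                stack.append((parent, False))
    return order


def grad(
    output: Tensor,
    inputs: Iterable[Tensor],
    create_graph: bool = False,
    grad_output: Tensor | None = None,
) -> list[Tensor]:
    """Gradients of ``output`` w.r.t. each tensor in ``inputs``.

    With ``create_graph=True`` the returned gradients are themselves
    differentiable graph nodes (needed for the gradient penalty).
    """
    inputs = list(inputs)
    if grad_output is None:
        grad_output = Tensor(np.ones_like(output.data))
    grads: dict[int, Tensor] = {id(output): grad_output}

    ctx = contextlib.nullcontext() if create_graph else no_grad()
    with ctx:
        for node in reversed(_toposort(output)):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            for parent, vjp in node._parents:
                contrib = vjp(g)
                prev = grads.get(id(parent))
                grads[id(parent)] = contrib if prev is None else prev + contrib
            if node in inputs:
                grads[id(node)] = g  # keep requested nodes
    # note: grads for intermediate nodes were popped during the sweep; inputs
    # that are leaves retain their accumulated gradient
    result = []
    for t in inputs:
        gt = grads.get(id(t))
        if gt is None:
            gt = Tensor(np.zeros_like(t.data))
        result.append(gt)
    return result
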