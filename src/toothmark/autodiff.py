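"""Minimal reverse-mode automatic differentiation over numpy arrays.

Supports higher-order derivatives: the backward pass is itself composed of
the same differentiable primitives, so gradients of gradients (as required
by second-order meta-gradients) come for free.  The engine is deliberately
small — dense/convolutional classification heads at desk scale are its only
customer — and trades raw speed for correctness and simplicity.

Conventions
-----------
* ``Tensor`` wraps a float64 ndarray.  Leaves created with ``track=True``
  participate in differentiation; everything else is a constant.
* All primitives broadcast like numpy; vector-Jacobian products reduce
  gradients back to the parent shape.
* ``no_grad()`` disables graph construction (used for frozen backbones and
  evaluation passes).
"""

from __future__ import annotations

from contextlib import contextmanager
from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "tensor",
    "no_grad",
    "add",
    "sub",
    "neg",
    "mul",
    "div",
    "matmul",
    "pow_const",
    "exp",
    "log",
    "sqrt",
    "relu",
    "sigmoid",
    "reshape",
    "transpose",
    "sum_",
    "mean_",
    "broadcast_to",
    "gather",
    "scatter",
    "grad",
    "log_softmax",
    "softmax",
    "cross_entropy",
]

_GRAD_ENABLED = True


@contextmanager
def no_grad():
    """Context manager suppressing graph construction."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


class Tensor:
    __slots__ = ("data", "track", "_parents")

    def __init__(self, data, track: bool = False, _parents: tuple = ()):
        self.data = np.asarray(data, dtype=np.float64)
        self.track = track
        self._parents = _parents

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data, track=False)

    def item(self) -> float:
        return float(self.data)

    # operator sugar --------------------------------------------------
    def __add__(self, other):
        return add(self, _as_tensor(other))

    def __radd__(self, other):
        return add(_as_tensor(other), self)

    def __sub__(self, other):
        return sub(self, _as_tensor(other))

    def __rsub__(self, other):
        return sub(_as_tensor(other), self)

    def __mul__(self, other):
        return mul(self, _as_tensor(other))

    def __rmul__(self, other):
        return mul(_as_tensor(other), self)

    def __truediv__(self, other):
        return div(self, _as_tensor(other))

    def __rtruediv__(self, other):
        return div(_as_tensor(other), self)

    def __neg__(self):
        return neg(self)

    def __matmul__(self, other):
        return matmul(self, _as_tensor(other))

    def __pow__(self, p):
        return pow_const(self, float(p))

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, track={self.track})"


def tensor(data, track: bool = False) -> Tensor:
    return Tensor(data, track=track)


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _node(data: np.ndarray, parents: Sequence[tuple]) -> Tensor:
    if _GRAD_ENABLED:
        live = tuple((p, fn) for p, fn in parents if p.track)
        if live:
            return Tensor(data, track=True, _parents=live)
    return Tensor(data)


def _sum_to(g: Tensor, shape: tuple) -> Tensor:
    """Reduce a broadcast gradient back to ``shape``."""
    while g.data.ndim > len(shape):
        g = sum_(g, axis=0)
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.data.shape[i] != 1)
    if axes:
        g = sum_(g, axis=axes, keepdims=True)
    return g


# ---------------------------------------------------------------------------
# primitives
# ---------------------------------------------------------------------------

def add(a: Tensor, b: Tensor) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    return _node(
        a.data + b.data,
        [
            (a, lambda g: _sum_to(g, a.shape)),
            (b, lambda g: _sum_to(g, b.shape)),
        ],
    )


def neg(a: Tensor) -> Tensor:
    return _node(-a.data, [(a, lambda g: neg(g))])


def sub(a: Tensor, b: Tensor) -> Tensor:
    return add(a, neg(_as_tensor(b)))


def mul(a: Tensor, b: Tensor) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    return _node(
        a.data * b.data,
        [
            (a, lambda g: _sum_to(mul(g, b), a.shape)),
            (b, lambda g: _sum_to(mul(g, a), b.shape)),
        ],
    )


def div(a: Tensor, b: Tensor) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    return _node(
        a.data / b.data,
        [
            (a, lambda g: _sum_to(div(g, b), a.shape)),
            (b, lambda g: _sum_to(neg(div(mul(g, a), mul(b, b))), b.shape)),
        ],
    )


def matmul(a: Tensor, b: Tensor) -> Tensor:
    if a.ndim != 2 or b.ndim != 2:
        raise ValueError(f"matmul expects 2-D operands, got {a.shape} @ {b.shape}")
    return _node(
        a.data @ b.data,
        [
            (a, lambda g: matmul(g, transpose(b))),
            (b, lambda g: matmul(transpose(a), g)),
        ],
    )


def pow_const(a: Tensor, p: float) -> Tensor:
    return _node(
        a.data ** p,
        [(a, lambda g: mul(g, mul(Tensor(p), pow_const(a, p - 1.0))))],
    )


def sqrt(a: Tensor) -> Tensor:
    return pow_const(a, 0.5)


def exp(a: Tensor) -> Tensor:
    out_data = np.exp(a.data)
    out = _node(out_data, [(a, lambda g: mul(g, out))])
    return out


def log(a: Tensor) -> Tensor:
    return _node(np.log(a.data), [(a, lambda g: div(g, a))])


def relu(a: Tensor) -> Tensor:
    mask = Tensor((a.data > 0).astype(np.float64))
    return _node(a.data * mask.data, [(a, lambda g: mul(g, mask))])


def sigmoid(a: Tensor) -> Tensor:
    out_data = 1.0 / (1.0 + np.exp(-a.data))
    out = _node(out_data, [(a, lambda g: mul(g, mul(out, sub(Tensor(1.0), out))))])
    return out


def reshape(a: Tensor, shape) -> Tensor:
    shape = tuple(shape)
    orig = a.shape
    return _node(a.data.reshape(shape), [(a, lambda g: reshape(g, orig))])


def transpose(a: Tensor, axes=None) -> Tensor:
    if axes is None:
        axes = tuple(reversed(range(a.ndim)))
    axes = tuple(axes)
    inv = tuple(np.argsort(axes))
    return _node(np.transpose(a.data, axes), [(a, lambda g: transpose(g, inv))])


def sum_(a: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    orig = a.shape
    if axis is None:
        axes = tuple(range(a.ndim))
    elif isinstance(axis, int):
        axes = (axis % a.ndim,)
    else:
        axes = tuple(ax % a.ndim for ax in axis)
    kept = tuple(1 if i in axes else s for i, s in enumerate(orig))

    def vjp(g):
        return broadcast_to(reshape(g, kept), orig)

    return _node(a.data.sum(axis=axes, keepdims=keepdims), [(a, vjp)])


def mean_(a: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    if axis is None:
        n = a.data.size
    else:
        axes = (axis,) if isinstance(axis, int) else tuple(axis)
        n = int(np.prod([a.shape[ax % a.ndim] for ax in axes]))
    return mul(sum_(a, axis=axis, keepdims=keepdims), Tensor(1.0 / n))


def broadcast_to(a: Tensor, shape) -> Tensor:
    shape = tuple(shape)
    return _node(
        np.broadcast_to(a.data, shape).copy(),
        [(a, lambda g: _sum_to(g, a.shape))],
    )


def gather(a: Tensor, idx: np.ndarray) -> Tensor:
    """Index into ``a.ravel()``; entries of ``idx`` equal to -1 read as 0.

    The adjoint is :func:`scatter`, making the pair usable for im2col-style
    convolution lowering (with -1 marking zero padding).
    """
    idx = np.asarray(idx)
    flat = a.data.ravel()
    safe = np.clip(idx, 0, flat.size - 1)
    out = flat[safe]
    if (idx < 0).any():
        out = np.where(idx < 0, 0.0, out)
    shape = a.shape
    return _node(out, [(a, lambda g: scatter(g, idx, shape))])


def scatter(g: Tensor, idx: np.ndarray, shape) -> Tensor:
    """Adjoint of :func:`gather`: sums ``g`` into a zero array of ``shape``."""
    idx = np.asarray(idx)
    size = int(np.prod(shape))
    flat_idx = idx.ravel()
    vals = g.data.ravel()
    mask = flat_idx >= 0
    if not mask.all():
        flat_idx = flat_idx[mask]
        vals = vals[mask]
    out = np.bincount(flat_idx, weights=vals, minlength=size).reshape(shape)
    return _node(out, [(g, lambda gg: gather(gg, idx))])


# ---------------------------------------------------------------------------
# reductions built from primitives
# ---------------------------------------------------------------------------

def log_softmax(z: Tensor, axis: int = -1) -> Tensor:
    # subtracting the (detached) row max is gradient-exact: softmax is
    # shift-invariant along the class axis
    m = Tensor(np.max(z.data, axis=axis, keepdims=True))
    shifted = sub(z, m)
    lse = log(sum_(exp(shifted), axis=axis, keepdims=True))
    return sub(shifted, lse)


def softmax(z: Tensor, axis: int = -1) -> Tensor:
    return exp(log_softmax(z, axis=axis))


def cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean categorical cross-entropy from logits and integer labels."""
    labels = np.asarray(labels, dtype=np.intp)
    n, c = logits.shape
    onehot = np.zeros((n, c))
    onehot[np.arange(n), labels] = 1.0
    lp = log_softmax(logits, axis=1)
    return neg(mean_(sum_(mul(lp, Tensor(onehot)), axis=1)))


# ---------------------------------------------------------------------------
# differentiation
# ---------------------------------------------------------------------------

def grad(
    out: Tensor,
    wrt: Iterable[Tensor],
    create_graph: bool = False,
) -> list[Tensor]:
    """Gradients of scalar ``out`` w.r.t. each tensor in ``wrt``.

    With ``create_graph=True`` the returned gradients are themselves
    differentiable (the backward pass records new graph nodes), enabling
    second-order derivatives.
    """
    wrt = list(wrt)
    if out.data.size != 1:
        raise ValueError("grad expects a scalar output")

    order: list[Tensor] = []
    seen: set[int] = set()
    stack = [(out, False)]
    while stack:
        node, done = stack.pop()
        if done:
            order.append(node)
            continue
        if id(node) in seen or not node.track:
            continue
        seen.add(id(node))
        stack.append((node, True))
        for p, _ in node._parents:
            stack.append((p, False))

    grads: dict[int, Tensor] = {id(out): Tensor(np.ones_like(out.data))}

    def run():
        for node in reversed(order):
            g = grads.get(id(node))
            if g is None:
                continue
            for parent, vjp in node._parents:
                pg = vjp(g)
                acc = grads.get(id(parent))
                grads[id(parent)] = pg if acc is None else add(acc, pg)

    if create_graph:
        run()
    else:
        with no_grad():
            run()

    result = []
    for w in wrt:
        g = grads.get(id(w))
        if g is None:
            g = Tensor(np.zeros_like(w.data))
        elif not create_graph:
            g = g.detach()
        result.append(g)
    return result
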