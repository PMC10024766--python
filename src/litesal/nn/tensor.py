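"""Reverse-mode automatic differentiation on float32 numpy buffers.

The saliency network needs only a small, closed set of differentiable
operations (pointwise nonlinearities, reductions, convolutions, pooling and
bilinear resampling), so rather than pulling in a full deep-learning
framework the package carries its own minimal tape: every operation builds a
``Tensor`` that remembers its parents and a closure that routes the upstream
gradient to them.  :meth:`Tensor.backward` runs the closures in reverse
topological order.

Structured operations (convolution, pooling, resampling) live in
:mod:`litesal.nn.functional`; this module holds the tensor type plus the
pointwise and reduction primitives.
"""

from __future__ import annotations

import contextlib
from typing import Iterable, Sequence

import numpy as np

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    """Disable graph construction (inference / running-stat updates)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def is_grad_enabled() -> bool:
    return _GRAD_ENABLED


class Tensor:
    """A float32 array plus the bookkeeping needed for backpropagation."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float32)
        self.requires_grad = bool(requires_grad)
        self.grad: np.ndarray | None = None
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # -- introspection -----------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    @property
    def size(self) -> int:
        return self.data.size

    def numpy(self) -> np.ndarray:
        return self.data

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def __repr__(self) -> str:  # pragma: no cover - debug aid
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    # -- autograd ----------------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        """Backpropagate from this tensor (default seed: ones)."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS: graphs are deep (hundreds of nodes)
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        if grad is None:
            grad = np.ones_like(self.data)
        self.grad = np.asarray(grad, dtype=np.float32)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward()
            if node._parents:
                # single-shot tape: drop the upstream gradient, the closure
                # (and anything it captured) and the parent links as soon as
                # this node is done, so activations free during the sweep
                node.grad = None
                node._backward = None
                node._parents = ()

    # -- operator sugar ----------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __neg__(self):
        return mul(self, -1.0)

    def __sub__(self, other):
        return add(self, mul(as_tensor(other), -1.0))

    def __rsub__(self, other):
        return add(as_tensor(other), mul(self, -1.0))

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __pow__(self, exponent: float):
        return pow_scalar(self, exponent)

    def reshape(self, *shape) -> "Tensor":
        return reshape(self, shape if len(shape) > 1 else shape[0])

    def sum(self, axis=None, keepdims=False) -> "Tensor":
        return tsum(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims=False) -> "Tensor":
        return tmean(self, axis=axis, keepdims=keepdims)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _accum(t: Tensor, g: np.ndarray) -> None:
    if t.grad is None:
        t.grad = g.astype(np.float32, copy=False)
    else:
        t.grad = t.grad + g


def _unbroadcast(g: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `g` down to `shape` (inverse of numpy broadcasting)."""
    if g.shape == shape:
        return g
    extra = g.ndim - len(shape)
    if extra > 0:
        g = g.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, (gs, ss) in enumerate(zip(g.shape, shape)) if ss == 1 and gs != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g.reshape(shape)


def build(data: np.ndarray, parents: Sequence[Tensor], backward) -> Tensor:
    """Wrap `data` as the output of an op; attach the tape entry if needed."""
    needs = _GRAD_ENABLED and any(p.requires_grad for p in parents)
    out = Tensor(data, requires_grad=needs)
    if needs:
        out._parents = tuple(parents)
        out._backward = backward
    return out


# ---------------------------------------------------------------------------
# pointwise primitives
# ---------------------------------------------------------------------------

def add(x, y) -> Tensor:
    x, y = as_tensor(x), as_tensor(y)
    out: Tensor = None  # type: ignore[assignment]

    def bwd():
        if x.requires_grad:
            _accum(x, _unbroadcast(out.grad, x.shape))
        if y.requires_grad:
            _accum(y, _unbroadcast(out.grad, y.shape))

    out = build(x.data + y.data, (x, y), bwd)
    return out


def mul(x, y) -> Tensor:
    x, y = as_tensor(x), as_tensor(y)
    out: Tensor = None  # type: ignore[assignment]

    def bwd():
        if x.requires_grad:
            _accum(x, _unbroadcast(out.grad * y.data, x.shape))
        if y.requires_grad:
            _accum(y, _unbroadcast(out.grad * x.data, y.shape))

    out = build(x.data * y.data, (x, y), bwd)
    return out


def pow_scalar(x: Tensor, exponent: float) -> Tensor:
    x = as_tensor(x)
    data = x.data ** np.float32(exponent)
    out: Tensor = None  # type: ignore[assignment]

    def bwd():
        if x.requires_grad:
            _accum(x, out.grad * exponent * x.data ** np.float32(exponent - 1.0))

    out = build(data, (x,), bwd)
    return out


def exp(x: Tensor) -> Tensor:
    x = as_tensor(x)
    data = np.exp(x.data)
    out: Tensor = None  # type: ignore[assignment]

    def bwd():
        if x.requires_grad:
            _accum(x, out.grad * data)

    out = build(data, (x,), bwd)
    return out


def log(x: Tensor) -> Tensor:
    x = as_tensor(x)
    out: Tensor = None  # type: ignore[assignment]

    def bwd():
        if x.requires_grad:
            _accum(x, out.grad / x.data)

    out = build(np.log(x.data), (x,), bwd)
    return out


def clip(x: Tensor, lo: float, hi: float) -> Tensor:
    """Clamp to [lo, hi]; the gradient passes only through the interior."""
    x = as_tensor(x)
    mask = (x.data >= lo) & (x.data <= hi)
    out: Tensor = None  # type: ignore[assignment]

    def bwd():
        if x.requires_grad:
            _accum(x, out.grad * mask)

    out = build(np.clip(x.data, lo, hi), (x,), bwd)
    return out


def relu(x: Tensor) -> Tensor:
    x = as_tensor(x)
    mask = x.data > 0
    out: Tensor = None  # type: ignore[assignment]

    def bwd():
        if x.requires_grad:
            _accum(x, out.grad * mask)

    out = build(x.data * mask, (x,), bwd)
    return out


def sigmoid(x: Tensor) -> Tensor:
    x = as_tensor(x)
    # numerically stable logistic
    d = x.data
    data = np.empty_like(d)
    pos = d >= 0
    data[pos] = 1.0 / (1.0 + np.exp(-d[pos]))
    ez = np.exp(d[~pos])
    data[~pos] = ez / (1.0 + ez)
    out: Tensor = None  # type: ignore[assignment]

    def bwd():
        if x.requires_grad:
            _accum(x, out.grad * data * (1.0 - data))

    out = build(data, (x,), bwd)
    return out


def maximum(x: Tensor, y: Tensor) -> Tensor:
    """Elementwise max; ties split the gradient evenly."""
    x, y = as_tensor(x), as_tensor(y)
    data = np.maximum(x.data, y.data)
    out: Tensor = None  # type: ignore[assignment]

    def bwd():
        gx = np.where(x.data > y.data, 1.0, np.where(x.data == y.data, 0.5, 0.0))
        if x.requires_grad:
            _accum(x, _unbroadcast(out.grad * gx, x.shape))
        if y.requires_grad:
            _accum(y, _unbroadcast(out.grad * (1.0 - gx), y.shape))

    out = build(data, (x, y), bwd)
    return out


# ---------------------------------------------------------------------------
# reductions / shape
# ---------------------------------------------------------------------------

def tsum(x: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    x = as_tensor(x)
    data = x.data.sum(axis=axis, keepdims=keepdims)
    out: Tensor = None  # type: ignore[assignment]

    def bwd():
        if not x.requires_grad:
            return
        g = out.grad
        if axis is not None and not keepdims:
            axes = (axis,) if np.isscalar(axis) else tuple(axis)
            g = np.expand_dims(g, tuple(a % x.ndim for a in axes))
        _accum(x, np.broadcast_to(g, x.shape).astype(np.float32))

    out = build(data, (x,), bwd)
    return out


def tmean(x: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    n = x.data.size if axis is None else np.prod(
        [x.data.shape[a % x.ndim] for a in ((axis,) if np.isscalar(axis) else tuple(axis))]
    )
    return mul(tsum(x, axis=axis, keepdims=keepdims), 1.0 / float(n))


def amax(x: Tensor, axis: int, keepdims: bool = False) -> Tensor:
    """Max along one axis; the gradient flows to the first argmax."""
    x = as_tensor(x)
    idx = np.argmax(x.data, axis=axis)
    data = np.take_along_axis(x.data, np.expand_dims(idx, axis), axis=axis)
    if not keepdims:
        data = np.squeeze(data, axis=axis)
    out: Tensor = None  # type: ignore[assignment]

    def bwd():
        if not x.requires_grad:
            return
        g = out.grad
        if not keepdims:
            g = np.expand_dims(g, axis)
        gx = np.zeros_like(x.data)
        np.put_along_axis(gx, np.expand_dims(idx, axis), g, axis=axis)
        _accum(x, gx)

    out = build(data, (x,), bwd)
    return out


def reshape(x: Tensor, shape) -> Tensor:
    x = as_tensor(x)
    out: Tensor = None  # type: ignore[assignment]

    def bwd():
        if x.requires_grad:
            _accum(x, out.grad.reshape(x.shape))

    out = build(x.data.reshape(shape), (x,), bwd)
    return out


def concat(tensors: Iterable[Tensor], axis: int = 1) -> Tensor:
    ts = [as_tensor(t) for t in tensors]
    sizes = [t.shape[axis] for t in ts]
    out: Tensor = None  # type: ignore[assignment]

    def bwd():
        offset = 0
        for t, s in zip(ts, sizes):
            if t.requires_grad:
                sl = [slice(None)] * out.grad.ndim
                sl[axis] = slice(offset, offset + s)
                _accum(t, out.grad[tuple(sl)])
            offset += s

    out = build(np.concatenate([t.data for t in ts], axis=axis), ts, bwd)
    return out


def matmul(x: Tensor, w: Tensor) -> Tensor:
    """2-D matrix product (N,I) @ (I,O)."""
    x, w = as_tensor(x), as_tensor(w)
    out: Tensor = None  # type: ignore[assignment]

    def bwd():
        if x.requires_grad:
            _accum(x, out.grad @ w.data.T)
        if w.requires_grad:
            _accum(w, x.data.T @ out.grad)

    out = build(x.data @ w.data, (x, w), bwd)
    return out


def softmax_list(logits: Sequence[Tensor]) -> list[Tensor]:
    """Softmax across a list of same-shaped tensors (returned per entry)."""
    m = logits[0]
    for l in logits[1:]:
        m = maximum(m, l)
    m = m.detach()  # max subtraction is a constant shift; keeps exp stable
    exps = [exp(l - m) for l in logits]
    z = exps[0]
    for e in exps[1:]:
        z = add(z, e)
    zinv = pow_scalar(z, -1.0)
    return [mul(e, zinv) for e in exps]
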