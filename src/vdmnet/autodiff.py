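"""Minimal reverse-mode automatic differentiation on numpy arrays.

The segmentation network in this package is small enough to train on a CPU,
so instead of depending on a deep-learning framework the package carries a
compact tape-based autodiff engine: a :class:`Tensor` wraps a float64 numpy
array, records the operations applied to it, and :meth:`Tensor.backward`
accumulates vector–Jacobian products into the gradients of the leaves.

Only the operations the network needs are implemented (elementwise
arithmetic, matmul, reductions, softmax, shape surgery, and the structured
convolution/pooling/sampling primitives in :mod:`vdmnet.nn`).  All math is
float64; desk-scale inputs keep this comfortably fast and it makes
finite-difference gradient checks tight.
"""

from __future__ import annotations

import contextlib

import numpy as np

__all__ = [
    "Tensor",
    "as_tensor",
    "no_grad",
    "concat",
    "matmul",
    "softmax",
    "leaky_relu",
    "sigmoid",
    "tanh",
    "exp",
    "log",
    "sqrt",
    "clip",
    "where_positive",
]

_grad_enabled = True


@contextlib.contextmanager
def no_grad():
    """Disable graph recording inside the context (inference / metrics)."""
    global _grad_enabled
    prev = _grad_enabled
    _grad_enabled = False
    try:
        yield
    finally:
        _grad_enabled = prev


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Reduce ``grad`` back to ``shape`` by summing broadcast axes."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, (g, s) in enumerate(zip(grad.shape, shape)) if s == 1 and g != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array plus the tape entry that produced it."""

    __array_priority__ = 100.0
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_vjp")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad)
        self.grad: np.ndarray | None = None
        self._parents: tuple = ()
        self._vjp = None

    # -- graph construction -------------------------------------------------

    @staticmethod
    def _op(data: np.ndarray, parents: tuple, vjp) -> "Tensor":
        out = Tensor(data)
        if _grad_enabled and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = parents
            out._vjp = vjp
        return out

    # -- backward -----------------------------------------------------------

    def backward(self, grad: np.ndarray | None = None) -> None:
        if not self.requires_grad:
            raise RuntimeError("backward() on a tensor that does not require grad")
        if grad is None:
            if self.data.size != 1:
                raise RuntimeError("grad must be supplied for non-scalar output")
            grad = np.ones_like(self.data)
        else:
            grad = np.asarray(grad, dtype=np.float64)

        # iterative post-order over the tape
        topo: list[Tensor] = []
        visited: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in visited:
                continue
            visited.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if p.requires_grad and id(p) not in visited:
                    stack.append((p, False))

        flowing: dict[int, np.ndarray] = {id(self): grad}
        for node in reversed(topo):
            g = flowing.pop(id(node), None)
            if g is None:
                continue
            if node._vjp is None:  # leaf
                node.grad = g if node.grad is None else node.grad + g
                continue
            for parent, pg in zip(node._parents, node._vjp(g)):
                if pg is None or not parent.requires_grad:
                    continue
                key = id(parent)
                if key in flowing:
                    flowing[key] = flowing[key] + pg
                else:
                    flowing[key] = pg

    def zero_grad(self) -> None:
        self.grad = None

    # -- convenience --------------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- elementwise arithmetic ----------------------------------------------

    def __add__(self, other):
        other = as_tensor(other)
        out = self.data + other.data
        return Tensor._op(
            out,
            (self, other),
            lambda g: (_unbroadcast(g, self.data.shape), _unbroadcast(g, other.data.shape)),
        )

    __radd__ = __add__

    def __neg__(self):
        return Tensor._op(-self.data, (self,), lambda g: (-g,))

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        out = self.data * other.data
        return Tensor._op(
            out,
            (self, other),
            lambda g: (
                _unbroadcast(g * other.data, self.data.shape),
                _unbroadcast(g * self.data, other.data.shape),
            ),
        )

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        out = self.data / other.data
        return Tensor._op(
            out,
            (self, other),
            lambda g: (
                _unbroadcast(g / other.data, self.data.shape),
                _unbroadcast(-g * self.data / other.data**2, other.data.shape),
            ),
        )

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, exponent: float):
        exponent = float(exponent)
        out = self.data**exponent
        return Tensor._op(
            out,
            (self,),
            lambda g: (g * exponent * self.data ** (exponent - 1.0),),
        )

    def __matmul__(self, other):
        return matmul(self, other)

    # -- reductions ----------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        out = self.data.sum(axis=axis, keepdims=keepdims)

        def vjp(g):
            gg = np.asarray(g)
            if axis is not None and not keepdims:
                gg = np.expand_dims(gg, axis)
            return (np.broadcast_to(gg, self.data.shape).copy(),)

        return Tensor._op(out, (self,), vjp)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in np.atleast_1d(axis)]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    # -- shape surgery ---------------------------------------------------------

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = self.data.reshape(shape)
        return Tensor._op(out, (self,), lambda g: (g.reshape(self.data.shape),))

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inverse = np.argsort(axes)
        out = self.data.transpose(axes)
        return Tensor._op(out, (self,), lambda g: (g.transpose(inverse),))

    def __getitem__(self, index):
        out = self.data[index]

        def vjp(g):
            full = np.zeros_like(self.data)
            full[index] = g
            return (full,)

        return Tensor._op(out, (self,), vjp)


def as_tensor(value) -> Tensor:
    return value if isinstance(value, Tensor) else Tensor(value)


# -- free functions -----------------------------------------------------------


def matmul(a: Tensor, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out = np.matmul(a.data, b.data)

    def vjp(g):
        ga = np.matmul(g, np.swapaxes(b.data, -1, -2))
        gb = np.matmul(np.swapaxes(a.data, -1, -2), g)
        return _unbroadcast(ga, a.data.shape), _unbroadcast(gb, b.data.shape)

    return Tensor._op(out, (a, b), vjp)


def exp(x: Tensor) -> Tensor:
    x = as_tensor(x)
    out = np.exp(x.data)
    return Tensor._op(out, (x,), lambda g: (g * out,))


def log(x: Tensor) -> Tensor:
    x = as_tensor(x)
    return Tensor._op(np.log(x.data), (x,), lambda g: (g / x.data,))


def sqrt(x: Tensor) -> Tensor:
    x = as_tensor(x)
    out = np.sqrt(x.data)
    return Tensor._op(out, (x,), lambda g: (g * 0.5 / out,))


def tanh(x: Tensor) -> Tensor:
    x = as_tensor(x)
    out = np.tanh(x.data)
    return Tensor._op(out, (x,), lambda g: (g * (1.0 - out**2),))


def sigmoid(x: Tensor) -> Tensor:
    x = as_tensor(x)
    xd = x.data
    out = np.where(xd >= 0, 1.0 / (1.0 + np.exp(-np.abs(xd))),
                   np.exp(-np.abs(xd)) / (1.0 + np.exp(-np.abs(xd))))
    return Tensor._op(out, (x,), lambda g: (g * out * (1.0 - out),))


def leaky_relu(x: Tensor, negative_slope: float = 0.01) -> Tensor:
    x = as_tensor(x)
    scale = np.where(x.data > 0, 1.0, negative_slope)
    return Tensor._op(x.data * scale, (x,), lambda g: (g * scale,))


def where_positive(cond: np.ndarray, a: Tensor, b: Tensor) -> Tensor:
    """Select ``a`` where ``cond`` (a plain array) is truthy, else ``b``."""
    a, b = as_tensor(a), as_tensor(b)
    mask = np.asarray(cond, dtype=bool)
    out = np.where(mask, a.data, b.data)
    return Tensor._op(
        out,
        (a, b),
        lambda g: (
            _unbroadcast(np.where(mask, g, 0.0), a.data.shape),
            _unbroadcast(np.where(mask, 0.0, g), b.data.shape),
        ),
    )


def clip(x: Tensor, lo: float, hi: float) -> Tensor:
    """Clamp with straight-zero gradient outside the interval."""
    x = as_tensor(x)
    out = np.clip(x.data, lo, hi)
    inside = (x.data > lo) & (x.data < hi)
    return Tensor._op(out, (x,), lambda g: (g * inside,))


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    x = as_tensor(x)
    shifted = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    out = e / e.sum(axis=axis, keepdims=True)

    def vjp(g):
        dot = (g * out).sum(axis=axis, keepdims=True)
        return (out * (g - dot),)

    return Tensor._op(out, (x,), vjp)


def concat(tensors, axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def vjp(g):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor._op(out, tuple(tensors), vjp)
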