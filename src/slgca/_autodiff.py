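"""Minimal reverse-mode automatic differentiation on numpy arrays.

The training objective combines graph convolutions, an InfoNCE-style
neighborhood contrastive term and a feature-decorrelation term; all of them
are compositions of a dozen primitive array operations.  This module provides
exactly those primitives as a :class:`Tensor` wrapper around ``numpy.ndarray``
with reverse-mode gradients, which is all the optimiser needs.

Conventions
-----------
* Everything is float64.  Matmul is 2-D only.
* Broadcasting follows numpy; gradients are summed back over broadcast axes.
* Constants (plain arrays / scalars) may appear on either side of an
  operator; they are wrapped on the fly and receive no gradient.

The public helpers :func:`relu`, :func:`sigmoid`, :func:`exp`, :func:`log`,
:func:`sqrt` and :func:`tsum` dispatch on input type, so model and loss code
written with them runs unchanged on plain numpy arrays (inference, tests)
and on Tensors (training).
"""

from __future__ import annotations

from typing import Any

import numpy as np
import scipy.sparse as sp
from scipy import special

__all__ = [
    "Tensor",
    "asdata",
    "is_tensor",
    "matmul",
    "diag",
    "relu",
    "sigmoid",
    "exp",
    "log",
    "sqrt",
    "tsum",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` over the axes numpy broadcast so it matches ``shape``."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array with a gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    # keep numpy from consuming us in mixed expressions: binary ufuncs on
    # (ndarray, Tensor) then fall back to our reflected dunder methods
    __array_ufunc__ = None
    __array_priority__ = 1000

    def __init__(self, data: Any, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # ------------------------------------------------------------------ util
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    @staticmethod
    def _wrap(x: Any) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    @staticmethod
    def _node(data: np.ndarray, parents: tuple["Tensor", ...], backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = parents
            out._backward = backward
        return out

    def _accumulate(self, g: np.ndarray, own: bool = True) -> None:
        """Add ``g`` to the gradient; ``own=False`` marks a shared buffer.

        Backward closures pass ``own=True`` for arrays they computed fresh
        (safe to store and mutate) and ``own=False`` for pass-through
        references to a child's gradient, which must be copied before an
        in-place accumulation could alias another node's gradient.
        """
        if not self.requires_grad:
            return
        if self.grad is None:
            self.grad = g if own else g.copy()
        else:
            self.grad += g

    def _acc_bc(self, g: np.ndarray) -> None:
        ub = _unbroadcast(g, self.data.shape)
        self._accumulate(ub, own=ub is not g)

    # ------------------------------------------------------------ arithmetic
    def __add__(self, other: Any) -> "Tensor":
        a, b = self, Tensor._wrap(other)
        data = a.data + b.data

        def backward(g: np.ndarray) -> None:
            a._acc_bc(g)
            b._acc_bc(g)

        return Tensor._node(data, (a, b), backward)

    def __radd__(self, other: Any) -> "Tensor":
        return Tensor._wrap(other).__add__(self)

    def __sub__(self, other: Any) -> "Tensor":
        a, b = self, Tensor._wrap(other)
        data = a.data - b.data

        def backward(g: np.ndarray) -> None:
            a._acc_bc(g)
            b._acc_bc(-g)

        return Tensor._node(data, (a, b), backward)

    def __rsub__(self, other: Any) -> "Tensor":
        return Tensor._wrap(other).__sub__(self)

    def __neg__(self) -> "Tensor":
        a = self

        def backward(g: np.ndarray) -> None:
            a._accumulate(-g)

        return Tensor._node(-a.data, (a,), backward)

    def __mul__(self, other: Any) -> "Tensor":
        a, b = self, Tensor._wrap(other)
        data = a.data * b.data

        def backward(g: np.ndarray) -> None:
            a._acc_bc(g * b.data)
            b._acc_bc(g * a.data)

        return Tensor._node(data, (a, b), backward)

    def __rmul__(self, other: Any) -> "Tensor":
        return Tensor._wrap(other).__mul__(self)

    def __truediv__(self, other: Any) -> "Tensor":
        a, b = self, Tensor._wrap(other)
        data = a.data / b.data

        def backward(g: np.ndarray) -> None:
            a._acc_bc(g / b.data)
            b._acc_bc(-g * a.data / (b.data * b.data))

        return Tensor._node(data, (a, b), backward)

    def __rtruediv__(self, other: Any) -> "Tensor":
        return Tensor._wrap(other).__truediv__(self)

    def __pow__(self, n: float) -> "Tensor":
        if not np.isscalar(n):
            raise TypeError("Tensor ** exponent must be a scalar")
        a = self
        data = a.data ** n

        def backward(g: np.ndarray) -> None:
            a._accumulate(g * n * a.data ** (n - 1))

        return Tensor._node(data, (a,), backward)

    def __matmul__(self, other: Any) -> "Tensor":
        a, b = self, Tensor._wrap(other)
        if a.data.ndim != 2 or b.data.ndim != 2:
            raise ValueError("Tensor matmul supports 2-D operands only")
        data = a.data @ b.data

        def backward(g: np.ndarray) -> None:
            a._accumulate(g @ b.data.T)
            b._accumulate(a.data.T @ g)

        return Tensor._node(data, (a, b), backward)

    def __rmatmul__(self, other: Any) -> "Tensor":
        return Tensor._wrap(other).__matmul__(self)

    def diag(self) -> "Tensor":
        """Diagonal of a square matrix as a vector."""
        a = self
        n = a.data.shape[0]

        def backward(g: np.ndarray) -> None:
            out = np.zeros_like(a.data)
            np.fill_diagonal(out, g)
            a._accumulate(out)

        return Tensor._node(np.diagonal(a.data).copy(), (a,), backward)

    # ------------------------------------------------------------- reshaping
    @property
    def T(self) -> "Tensor":
        a = self

        def backward(g: np.ndarray) -> None:
            a._accumulate(g.T, own=False)

        return Tensor._node(a.data.T, (a,), backward)

    def sum(self, axis: int | None = None, keepdims: bool = False) -> "Tensor":
        a = self
        data = a.data.sum(axis=axis, keepdims=keepdims)

        def backward(g: np.ndarray) -> None:
            if axis is None:
                a._accumulate(np.broadcast_to(g, a.data.shape).copy())
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                a._accumulate(np.broadcast_to(gg, a.data.shape).copy())

        return Tensor._node(data, (a,), backward)

    # -------------------------------------------------------------- backward
    def backward(self) -> None:
        """Backpropagate from this (scalar) tensor through the graph."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar tensor")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS: loss graphs can be deep
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        for node in topo:
            if node is not self:
                node.grad = None
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)


# ---------------------------------------------------------------- dispatch


def is_tensor(x: Any) -> bool:
    return isinstance(x, Tensor)


def asdata(x: Any) -> np.ndarray:
    """The underlying numpy array of a Tensor, or ``asarray`` of anything else."""
    if isinstance(x, Tensor):
        return x.data
    if sp.issparse(x):
        return x
    return np.asarray(x, dtype=np.float64)


def matmul(a: Any, b: Any) -> Any:
    """Matrix product where either operand may be a scipy.sparse constant.

    Sparse operands never carry gradients — they are the (fixed) adjacency
    matrices; the Tensor operand receives ``S.T @ g`` / ``g @ S.T``.
    """
    if sp.issparse(a) and isinstance(b, Tensor):
        data = a @ b.data

        def backward(g: np.ndarray) -> None:
            b._accumulate(a.T @ g)

        return Tensor._node(np.asarray(data), (b,), backward)
    if isinstance(a, Tensor) and sp.issparse(b):
        data = a.data @ b

        def backward(g: np.ndarray) -> None:
            a._accumulate(g @ b.T)

        return Tensor._node(np.asarray(data), (a,), backward)
    return a @ b


def diag(x: Any) -> Any:
    """Diagonal of a square matrix (vector); differentiable for Tensors."""
    if isinstance(x, Tensor):
        return x.diag()
    return np.diagonal(np.asarray(x)).copy()


def _unary(x: Any, fwd, dfwd) -> Any:
    """Apply elementwise ``fwd`` with derivative ``dfwd(out, xdata)``."""
    if isinstance(x, Tensor):
        data = fwd(x.data)

        def backward(g: np.ndarray) -> None:
            x._accumulate(g * dfwd(data, x.data))

        return Tensor._node(data, (x,), backward)
    return fwd(np.asarray(x, dtype=np.float64))


def relu(x: Any) -> Any:
    return _unary(x, lambda d: np.maximum(d, 0.0), lambda out, d: (d > 0).astype(np.float64))


def sigmoid(x: Any) -> Any:
    return _unary(x, special.expit, lambda out, d: out * (1.0 - out))


def exp(x: Any) -> Any:
    return _unary(x, np.exp, lambda out, d: out)


def log(x: Any) -> Any:
    return _unary(x, np.log, lambda out, d: 1.0 / d)


def sqrt(x: Any) -> Any:
    return _unary(x, np.sqrt, lambda out, d: 0.5 / out)


def tsum(x: Any, axis: int | None = None, keepdims: bool = False) -> Any:
    if isinstance(x, Tensor):
        return x.sum(axis=axis, keepdims=keepdims)
    return np.asarray(x, dtype=np.float64).sum(axis=axis, keepdims=keepdims)
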