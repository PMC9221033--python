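"""Reverse-mode automatic differentiation over NumPy arrays.

This is the package's numeric core: a small define-by-run tape in double
precision. Every model forward pass builds a graph of :class:`Tensor` nodes;
``Tensor.backward`` runs the reverse sweep and accumulates ``.grad`` on every
node created with ``requires_grad=True``. Double precision keeps the
finite-difference gradient checks in the test suite meaningful (relative
errors around 1e-7 rather than float32's 1e-2).

Only the operations the secondary-structure models need are provided:
broadcasting arithmetic, matmul, the sigmoid/tanh/relu/exp/log
nonlinearities, axis reductions, concatenation, zero padding along the
sequence axis, fancy row gathering (the im2col step of the convolutions),
basic slicing, and inverted dropout.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "concat",
    "pad_rows",
    "take",
    "dropout",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape`, undoing NumPy broadcasting."""
    if grad.shape == shape:
        return grad
    # sum over leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A node in the autodiff graph wrapping a float64 ndarray."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_bw")

    def __init__(
        self,
        data,
        requires_grad: bool = False,
        _parents: tuple["Tensor", ...] = (),
        _bw: Callable[[np.ndarray], None] | None = None,
    ):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in _parents)
        self._parents = _parents if self.requires_grad else ()
        self._bw = _bw if self.requires_grad else None

    # ------------------------------------------------------------------ infra
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(grad, dtype=np.float64, copy=True)
        else:
            self.grad += grad

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self, grad: np.ndarray | float | None = None) -> None:
        """Reverse sweep from this node.

        For scalar outputs `grad` defaults to 1. A non-None `grad` seeds the
        sweep (used to weight per-protein losses inside a batch).
        """
        if not self.requires_grad:
            raise RuntimeError("backward() on a tensor that does not require grad")
        if grad is None:
            if self.data.size != 1:
                raise RuntimeError("backward() without a seed grad needs a scalar output")
            grad = np.ones_like(self.data)
        grad = np.broadcast_to(np.asarray(grad, dtype=np.float64), self.data.shape)

        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS; graphs can be thousands of nodes deep
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))

        self._accumulate(grad)
        for node in reversed(topo):
            if node._bw is not None and node.grad is not None:
                node._bw(node.grad)

    # ------------------------------------------------------------- arithmetic
    @staticmethod
    def _lift(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other) -> "Tensor":
        other = self._lift(other)
        out_data = self.data + other.data

        def bw(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.data.shape))

        return Tensor(out_data, _parents=(self, other), _bw=bw)

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        def bw(g: np.ndarray) -> None:
            self._accumulate(-g)

        return Tensor(-self.data, _parents=(self,), _bw=bw)

    def __sub__(self, other) -> "Tensor":
        return self + (-self._lift(other))

    def __rsub__(self, other) -> "Tensor":
        return self._lift(other) + (-self)

    def __mul__(self, other) -> "Tensor":
        other = self._lift(other)
        out_data = self.data * other.data

        def bw(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.data.shape))

        return Tensor(out_data, _parents=(self, other), _bw=bw)

    __rmul__ = __mul__

    def __truediv__(self, other) -> "Tensor":
        other = self._lift(other)
        out_data = self.data / other.data

        def bw(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(
                    _unbroadcast(-g * self.data / other.data**2, other.data.shape)
                )

        return Tensor(out_data, _parents=(self, other), _bw=bw)

    def __matmul__(self, other) -> "Tensor":
        other = self._lift(other)
        out_data = self.data @ other.data

        def bw(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(g @ other.data.T)
            if other.requires_grad:
                other._accumulate(self.data.T @ g)

        return Tensor(out_data, _parents=(self, other), _bw=bw)

    # ---------------------------------------------------------- nonlinearities
    def sigmoid(self) -> "Tensor":
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def bw(g: np.ndarray) -> None:
            self._accumulate(g * out_data * (1.0 - out_data))

        return Tensor(out_data, _parents=(self,), _bw=bw)

    def tanh(self) -> "Tensor":
        out_data = np.tanh(self.data)

        def bw(g: np.ndarray) -> None:
            self._accumulate(g * (1.0 - out_data**2))

        return Tensor(out_data, _parents=(self,), _bw=bw)

    def relu(self) -> "Tensor":
        out_data = np.maximum(self.data, 0.0)

        def bw(g: np.ndarray) -> None:
            self._accumulate(g * (self.data > 0.0))

        return Tensor(out_data, _parents=(self,), _bw=bw)

    def exp(self) -> "Tensor":
        out_data = np.exp(self.data)

        def bw(g: np.ndarray) -> None:
            self._accumulate(g * out_data)

        return Tensor(out_data, _parents=(self,), _bw=bw)

    def log(self) -> "Tensor":
        def bw(g: np.ndarray) -> None:
            self._accumulate(g / self.data)

        return Tensor(np.log(self.data), _parents=(self,), _bw=bw)

    # --------------------------------------------------------------- reshaping
    def reshape(self, *shape) -> "Tensor":
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        in_shape = self.data.shape

        def bw(g: np.ndarray) -> None:
            self._accumulate(g.reshape(in_shape))

        return Tensor(self.data.reshape(shape), _parents=(self,), _bw=bw)

    def __getitem__(self, key) -> "Tensor":
        out_data = self.data[key]

        def bw(g: np.ndarray) -> None:
            full = np.zeros_like(self.data)
            np.add.at(full, key, g)
            self._accumulate(full)

        return Tensor(out_data, _parents=(self,), _bw=bw)

    # -------------------------------------------------------------- reductions
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out_data = self.data.sum(axis=axis, keepdims=keepdims)
        in_shape = self.data.shape

        def bw(g: np.ndarray) -> None:
            if axis is None:
                self._accumulate(np.broadcast_to(g, in_shape))
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, in_shape))

        return Tensor(out_data, _parents=(self,), _bw=bw)

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        if axis is None:
            n = self.data.size
        else:
            n = self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)


def concat(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = list(tensors)
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(g: np.ndarray) -> None:
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(a, b)
                t._accumulate(g[tuple(idx)])

    return Tensor(out_data, _parents=tuple(tensors), _bw=bw)


def pad_rows(x: Tensor, before: int, after: int) -> Tensor:
    """Zero-pad a (n, C) tensor along axis 0."""
    n = x.data.shape[0]
    pad_width = ((before, after),) + ((0, 0),) * (x.data.ndim - 1)
    out_data = np.pad(x.data, pad_width)

    def bw(g: np.ndarray) -> None:
        x._accumulate(g[before : before + n])

    return Tensor(out_data, _parents=(x,), _bw=bw)


def take(x: Tensor, indices: np.ndarray) -> Tensor:
    """Gather rows of a (n, C) tensor: output shape indices.shape + (C,)."""
    indices = np.asarray(indices)
    out_data = x.data[indices]

    def bw(g: np.ndarray) -> None:
        full = np.zeros_like(x.data)
        np.add.at(full, indices.reshape(-1), g.reshape(-1, x.data.shape[-1]))
        x._accumulate(full)

    return Tensor(out_data, _parents=(x,), _bw=bw)


def dropout(x: Tensor, rate: float, rng: np.random.Generator) -> Tensor:
    """Inverted dropout: active only when called (callers gate on training mode)."""
    if rate <= 0.0:
        return x
    keep = 1.0 - rate
    mask = (rng.random(x.data.shape) < keep) / keep
    return x * Tensor(mask)


def parameters_of(tensors: Iterable[Tensor]) -> list[Tensor]:
    return [t for t in tensors if t.requires_grad]
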