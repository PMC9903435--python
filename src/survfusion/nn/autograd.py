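"""Reverse-mode automatic differentiation over NumPy float32 arrays.

The graph is built eagerly: every operation returns a :class:`Tensor` whose
``_backward`` closure scatters the output gradient to its parents.  Heavy
operations (convolution, pooling) live in :mod:`survfusion.nn.layers` and
register themselves through the same mechanism via :func:`make_node`.
"""

from __future__ import annotations

import contextlib
from typing import Callable, Iterable

import numpy as np
from scipy import special

_GRAD_ENABLED = [True]


@contextlib.contextmanager
def no_grad():
    """Disable graph construction (inference mode)."""
    _GRAD_ENABLED.append(False)
    try:
        yield
    finally:
        _GRAD_ENABLED.pop()


def _as_f32(x) -> np.ndarray:
    a = np.asarray(x)
    return a.astype(np.float32) if a.dtype != np.float32 else a


def unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Reduce ``grad`` back to ``shape`` after NumPy broadcasting."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = _as_f32(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward: Callable[[], None] | None = None
        self._parents: tuple[Tensor, ...] = ()

    # -- bookkeeping -------------------------------------------------------
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

    def zero_grad(self) -> None:
        self.grad = None

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.astype(np.float32, copy=True)
        else:
            self.grad += g

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
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
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward()
            # free the graph as we go: interior gradients are consumed by
            # the node's own backward, and dropping the closure breaks the
            # node <-> closure reference cycle so memory is reclaimed
            # promptly instead of waiting for the cycle collector
            if node._parents:
                node.grad = None
                node._backward = None
                node._parents = ()

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- arithmetic --------------------------------------------------------
    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)

        def backward(out):
            if self.requires_grad:
                self._accumulate(unbroadcast(out.grad, self.shape))
            if other.requires_grad:
                other._accumulate(unbroadcast(out.grad, other.shape))

        return make_node(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(out):
            if self.requires_grad:
                self._accumulate(-out.grad)

        return make_node(-self.data, (self,), backward)

    def __sub__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self + (-other)

    def __rsub__(self, other):
        return Tensor(other) + (-self)

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)

        def backward(out):
            if self.requires_grad:
                self._accumulate(unbroadcast(out.grad * other.data, self.shape))
            if other.requires_grad:
                other._accumulate(unbroadcast(out.grad * self.data, other.shape))

        return make_node(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self * other.pow(-1.0)

    def pow(self, exponent: float):
        e = float(exponent)

        def backward(out):
            if self.requires_grad:
                self._accumulate(out.grad * e * self.data ** (e - 1.0))

        return make_node(self.data**e, (self,), backward)

    def matmul(self, other: "Tensor"):
        def backward(out):
            if self.requires_grad:
                self._accumulate(out.grad @ other.data.T)
            if other.requires_grad:
                other._accumulate(self.data.T @ out.grad)

        return make_node(self.data @ other.data, (self, other), backward)

    __matmul__ = matmul

    # -- reductions & shaping ---------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        def backward(out):
            if not self.requires_grad:
                return
            g = out.grad
            if axis is not None and not keepdims:
                ax = (axis,) if isinstance(axis, int) else tuple(axis)
                g = np.expand_dims(g, ax)
            self._accumulate(np.broadcast_to(g, self.shape).astype(np.float32))

        return make_node(self.data.sum(axis=axis, keepdims=keepdims), (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            count = self.data.size
        else:
            ax = (axis,) if isinstance(axis, int) else tuple(axis)
            count = int(np.prod([self.shape[a] for a in ax]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / count)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])

        def backward(out):
            if self.requires_grad:
                self._accumulate(out.grad.reshape(self.shape))

        return make_node(self.data.reshape(shape), (self,), backward)

    # -- nonlinearities ----------------------------------------------------
    def exp(self):
        out_data = np.exp(self.data)

        def backward(out):
            if self.requires_grad:
                self._accumulate(out.grad * out.data)

        return make_node(out_data, (self,), backward)

    def log(self):
        def backward(out):
            if self.requires_grad:
                self._accumulate(out.grad / self.data)

        return make_node(np.log(self.data), (self,), backward)

    def relu(self):
        def backward(out):
            if self.requires_grad:
                self._accumulate(out.grad * (out.data > 0))

        return make_node(np.maximum(self.data, 0), (self,), backward)

    def gelu(self):
        """Exact Gaussian error linear unit: x * Phi(x)."""
        x = self.data.astype(np.float64)
        phi_cdf = 0.5 * (1.0 + special.erf(x / np.sqrt(2.0)))
        out_data = (x * phi_cdf).astype(np.float32)

        def backward(out):
            if self.requires_grad:
                pdf = np.exp(-0.5 * x * x) / np.sqrt(2.0 * np.pi)
                self._accumulate(out.grad * (phi_cdf + x * pdf).astype(np.float32))

        return make_node(out_data, (self,), backward)


def make_node(
    data: np.ndarray,
    parents: tuple[Tensor, ...],
    backward: Callable,
) -> Tensor:
    """Create an output tensor wired into the graph.

    ``backward`` receives the output tensor and must scatter ``out.grad``
    into each parent that requires a gradient.
    """
    out = Tensor(data)
    if _GRAD_ENABLED[-1] and any(p.requires_grad for p in parents):
        out.requires_grad = True
        out._parents = tuple(parents)
        out._backward = lambda: backward(out)
    return out


def concat(tensors: Iterable[Tensor], axis: int = 1) -> Tensor:
    tensors = list(tensors)
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(out):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * out.grad.ndim
                sl[axis] = slice(a, b)
                t._accumulate(out.grad[tuple(sl)])

    return make_node(
        np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors), backward
    )
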