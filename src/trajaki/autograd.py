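"""Minimal reverse-mode automatic differentiation on NumPy arrays.

A small tape-based engine sufficient for training the window-level anomaly
transformer: broadcasting arithmetic, matmul, softmax, layer norm building
blocks, reductions, and ``detach`` for the stop-gradient phases of minimax
training. Gradients are accumulated by topological-order backward traversal.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "softmax", "relu", "concat"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (reverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum leading broadcast axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, size in enumerate(shape):
        if size == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """An array node on the autodiff tape."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")
    __array_priority__ = 100  # win over raw ndarrays in mixed expressions

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- construction helpers ------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        """A view of the same values cut off from the tape (stop-gradient)."""
        return Tensor(self.data, requires_grad=False)

    @staticmethod
    def _lift(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def _make(self, data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accum(self, grad: np.ndarray) -> None:
        if not self.requires_grad:
            return
        grad = _unbroadcast(np.asarray(grad, dtype=np.float64), self.data.shape)
        self.grad = grad if self.grad is None else self.grad + grad

    # -- arithmetic ----------------------------------------------------------
    def __add__(self, other):
        other = self._lift(other)

        def backward(g, a=self, b=other):
            a._accum(g)
            b._accum(g)

        return self._make(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __mul__(self, other):
        other = self._lift(other)

        def backward(g, a=self, b=other):
            a._accum(g * b.data)
            b._accum(g * a.data)

        return self._make(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __neg__(self):
        def backward(g, a=self):
            a._accum(-g)

        return self._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __truediv__(self, other):
        other = self._lift(other)

        def backward(g, a=self, b=other):
            a._accum(g / b.data)
            b._accum(-g * a.data / (b.data ** 2))

        return self._make(self.data / other.data, (self, other), backward)

    def __rtruediv__(self, other):
        return self._lift(other) / self

    def __pow__(self, p: float):
        def backward(g, a=self):
            a._accum(g * p * a.data ** (p - 1))

        return self._make(self.data ** p, (self,), backward)

    def __matmul__(self, other):
        other = self._lift(other)

        def backward(g, a=self, b=other):
            a._accum(g @ np.swapaxes(b.data, -1, -2))
            b._accum(np.swapaxes(a.data, -1, -2) @ g)

        return self._make(self.data @ other.data, (self, other), backward)

    # -- elementwise nonlinearities -------------------------------------------
    def exp(self):
        out_data = np.exp(self.data)

        def backward(g, a=self, od=out_data):
            a._accum(g * od)

        return self._make(out_data, (self,), backward)

    def log(self):
        def backward(g, a=self):
            a._accum(g / a.data)

        return self._make(np.log(self.data), (self,), backward)

    def tanh(self):
        out_data = np.tanh(self.data)

        def backward(g, a=self, od=out_data):
            a._accum(g * (1.0 - od ** 2))

        return self._make(out_data, (self,), backward)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def backward(g, a=self, od=out_data):
            a._accum(g * od * (1.0 - od))

        return self._make(out_data, (self,), backward)

    def clamp_min(self, floor: float):
        """Elementwise max(x, floor); gradient passes only where unclipped."""
        mask = (self.data >= floor).astype(np.float64)

        def backward(g, a=self, m=mask):
            a._accum(g * m)

        return self._make(np.maximum(self.data, floor), (self,), backward)

    def softplus(self):
        # log(1 + e^x), numerically stable
        out_data = np.logaddexp(0.0, self.data)

        def backward(g, a=self):
            a._accum(g / (1.0 + np.exp(-a.data)))

        return self._make(out_data, (self,), backward)

    # -- reductions & shaping --------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        def backward(g, a=self):
            gg = np.asarray(g)
            if axis is not None and not keepdims:
                gg = np.expand_dims(gg, axis)
            a._accum(np.broadcast_to(gg, a.data.shape))

        return self._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), backward)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        def backward(g, a=self):
            a._accum(np.asarray(g).reshape(a.data.shape))

        return self._make(self.data.reshape(*shape), (self,), backward)

    def transpose(self, *axes):
        inv = np.argsort(axes)

        def backward(g, a=self, inv=inv):
            a._accum(np.transpose(g, inv))

        return self._make(np.transpose(self.data, axes), (self,), backward)

    def __getitem__(self, idx):
        def backward(g, a=self, idx=idx):
            full = np.zeros_like(a.data)
            np.add.at(full, idx, g)
            a._accum(full)

        return self._make(self.data[idx], (self,), backward)

    # -- backward driver -------------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS; deep graphs exceed recursion limits
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self._accum(grad)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


def relu(x: Tensor) -> Tensor:
    mask = (x.data > 0).astype(np.float64)

    def backward(g, a=x, m=mask):
        a._accum(g * m)

    return x._make(x.data * mask, (x,), backward)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    """Softmax along `axis` with a fused, stable backward."""
    shifted = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    out_data = e / e.sum(axis=axis, keepdims=True)

    def backward(g, a=x, od=out_data):
        inner = (g * od).sum(axis=axis, keepdims=True)
        a._accum(od * (g - inner))

    return x._make(out_data, (x,), backward)


def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g, ts=tensors, off=offsets):
        for i, t in enumerate(ts):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(off[i], off[i + 1])
            t._accum(g[tuple(sl)])

    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis))
    if any(t.requires_grad for t in tensors):
        out.requires_grad = True
        out._parents = tuple(tensors)
        out._backward = backward
    return out
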