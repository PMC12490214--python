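"""Minimal reverse-mode automatic differentiation over numpy arrays.

A small tape-based engine providing exactly the operations the risk model
needs: broadcasting arithmetic, batched matmul, embedding gather, relu,
sigmoid, log/exp/sqrt, masked softmax, reductions, concatenation and a
pass-through clamp.  Gradients are accumulated by topological traversal of
the recorded graph.  Everything is float64 and single-threaded, so results
are bit-reproducible given identical inputs.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over prepended axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A node in the computation graph wrapping an ndarray."""

    __slots__ = ("value", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, value, requires_grad=False, parents=(), backward=None):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = parents
        self._backward = backward

    @property
    def shape(self):
        return self.value.shape

    # ---- graph construction helpers -------------------------------------

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = Tensor._lift(other)

        def backward(g, out):
            return (_unbroadcast(g, self.shape), _unbroadcast(g, other.shape))

        return Tensor(self.value + other.value, parents=(self, other), backward=backward)

    __radd__ = __add__

    def __neg__(self):
        return Tensor(-self.value, parents=(self,), backward=lambda g, out: (-g,))

    def __sub__(self, other):
        return self + (-Tensor._lift(other))

    def __rsub__(self, other):
        return Tensor._lift(other) + (-self)

    def __mul__(self, other):
        other = Tensor._lift(other)

        def backward(g, out):
            return (
                _unbroadcast(g * other.value, self.shape),
                _unbroadcast(g * self.value, other.shape),
            )

        return Tensor(self.value * other.value, parents=(self, other), backward=backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor._lift(other)

        def backward(g, out):
            return (
                _unbroadcast(g / other.value, self.shape),
                _unbroadcast(-g * self.value / other.value**2, other.shape),
            )

        return Tensor(self.value / other.value, parents=(self, other), backward=backward)

    def __rtruediv__(self, other):
        return Tensor._lift(other) / self

    def __matmul__(self, other):
        other = Tensor._lift(other)

        def backward(g, out):
            a, b = self.value, other.value
            ga = g @ np.swapaxes(b, -1, -2) if b.ndim > 1 else np.outer(g, b)
            gb = np.swapaxes(a, -1, -2) @ g if a.ndim > 1 else np.outer(a, g)
            return (_unbroadcast(ga, self.shape), _unbroadcast(gb, other.shape))

        return Tensor(self.value @ other.value, parents=(self, other), backward=backward)

    # ---- nonlinearities --------------------------------------------------

    def relu(self):
        mask = self.value > 0
        return Tensor(self.value * mask, parents=(self,), backward=lambda g, out: (g * mask,))

    def sigmoid(self):
        def backward(g, out):
            return (g * out.value * (1.0 - out.value),)

        return Tensor(expit(self.value), parents=(self,), backward=backward)

    def exp(self):
        return Tensor(np.exp(self.value), parents=(self,), backward=lambda g, out: (g * out.value,))

    def log(self):
        return Tensor(np.log(self.value), parents=(self,), backward=lambda g, out: (g / self.value,))

    def sqrt(self):
        def backward(g, out):
            return (g * 0.5 / out.value,)

        return Tensor(np.sqrt(self.value), parents=(self,), backward=backward)

    def clamp(self, lo, hi):
        """Clip values; gradient passes through only inside [lo, hi]."""
        inside = (self.value >= lo) & (self.value <= hi)
        return Tensor(
            np.clip(self.value, lo, hi),
            parents=(self,),
            backward=lambda g, out: (g * inside,),
        )

    # ---- reductions / reshaping -----------------------------------------

    def sum(self, axis=None, keepdims=False):
        def backward(g, out):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            return (np.broadcast_to(g, self.shape).copy(),)

        return Tensor(self.value.sum(axis=axis, keepdims=keepdims), parents=(self,), backward=backward)

    def mean(self, axis=None, keepdims=False):
        n = self.value.size if axis is None else self.value.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        return Tensor(
            self.value.reshape(*shape),
            parents=(self,),
            backward=lambda g, out: (g.reshape(self.shape),),
        )

    def transpose(self, *axes):
        inv = np.argsort(axes)
        return Tensor(
            self.value.transpose(*axes),
            parents=(self,),
            backward=lambda g, out: (g.transpose(*inv),),
        )


def concat(tensors, axis=0):
    tensors = [Tensor._lift(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g, out):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor(
        np.concatenate([t.value for t in tensors], axis=axis),
        parents=tuple(tensors),
        backward=backward,
    )


def gather(table: Tensor, idx: np.ndarray) -> Tensor:
    """Embedding lookup table[idx]; backward scatter-adds into the table."""
    idx = np.asarray(idx)

    def backward(g, out):
        gt = np.zeros_like(table.value)
        np.add.at(gt, idx.reshape(-1), g.reshape(-1, table.value.shape[-1]))
        return (gt,)

    return Tensor(table.value[idx], parents=(table,), backward=backward)


def softmax(x: Tensor, axis=-1, mask: np.ndarray | None = None) -> Tensor:
    """Numerically stable softmax; positions where mask==0 get zero weight."""
    if mask is not None:
        x = x + np.where(mask, 0.0, -1e30)
    shifted = x - x.value.max(axis=axis, keepdims=True)  # constant shift
    e = shifted.exp()
    return e / e.sum(axis=axis, keepdims=True)


def layer_norm(x: Tensor, gain: Tensor, bias: Tensor, eps: float = 1e-5) -> Tensor:
    mu = x.mean(axis=-1, keepdims=True)
    centered = x - mu
    var = (centered * centered).mean(axis=-1, keepdims=True)
    return centered / (var + eps).sqrt() * gain + bias


def backward(loss: Tensor) -> None:
    """Accumulate gradients of `loss` (a scalar) into every reachable node."""
    if loss.value.size != 1:
        raise ValueError("backward() expects a scalar loss")
    order: list[Tensor] = []
    seen: set[int] = set()
    stack = [(loss, False)]
    while stack:  # iterative DFS post-order
        node, processed = stack.pop()
        if processed:
            order.append(node)
            continue
        if id(node) in seen:
            continue
        seen.add(id(node))
        stack.append((node, True))
        for p in node._parents:
            if p.requires_grad and id(p) not in seen:
                stack.append((p, False))
    loss.grad = np.ones_like(loss.value)
    for node in reversed(order):
        if node._backward is None or node.grad is None:
            continue
        grads = node._backward(node.grad, node)
        for parent, g in zip(node._parents, grads):
            if not parent.requires_grad:
                continue
            if parent.grad is None:
                parent.grad = np.zeros_like(parent.value)
            parent.grad += g


def zero_grads(params) -> None:
    for p in params:
        p.grad = None
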