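"""Minimal reverse-mode automatic differentiation on numpy arrays.

A small tape-based engine covering exactly the operations the embedding and
risk networks need: affine maps, elementwise nonlinearities, softmax,
reductions, concatenation, row gathering and a gradient-reversal identity
for adversarial training.  Gradients are validated against central finite
differences in the test suite.

Not a general framework: 2-D matmul only, float64 throughout.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "gather_rows", "grad_reverse"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape`, undoing numpy broadcasting."""
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
    """Node in the computation tape.

    Wraps a float64 ndarray; `requires_grad` marks leaves whose gradient is
    wanted.  Interior nodes record their parents and a backward closure.
    """

    __slots__ = ("value", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, value, requires_grad: bool = False,
                 _parents=(), _backward=None):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = None
        self.requires_grad = requires_grad or any(
            p.requires_grad for p in _parents)
        self._parents = _parents
        self._backward = _backward

    # -- helpers ---------------------------------------------------------
    @property
    def shape(self):
        return self.value.shape

    @staticmethod
    def _lift(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def _make(self, value, parents, backward):
        return Tensor(value, _parents=parents, _backward=backward)

    # -- arithmetic ------------------------------------------------------
    def __add__(self, other):
        other = self._lift(other)
        out_val = self.value + other.value

        def backward(g):
            return (_unbroadcast(g, self.value.shape),
                    _unbroadcast(g, other.value.shape))

        return self._make(out_val, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        return self._make(-self.value, (self,), lambda g: (-g,))

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out_val = self.value * other.value

        def backward(g):
            return (_unbroadcast(g * other.value, self.value.shape),
                    _unbroadcast(g * self.value, other.value.shape))

        return self._make(out_val, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, scalar):
        if isinstance(scalar, Tensor):
            raise TypeError("division only by python/numpy scalars")
        return self * (1.0 / scalar)

    def matmul(self, other):
        other = self._lift(other)
        a, b = self.value, other.value
        out_val = a @ b

        def backward(g):
            return (g @ b.T, a.T @ g)

        return self._make(out_val, (self, other), backward)

    __matmul__ = matmul

    def transpose(self):
        """Matrix transpose (2-D)."""
        return self._make(self.value.T, (self,), lambda g: (g.T,))

    @property
    def T(self):
        return self.transpose()

    # -- elementwise nonlinearities -------------------------------------
    def tanh(self):
        y = np.tanh(self.value)
        return self._make(y, (self,), lambda g: (g * (1.0 - y * y),))

    def relu(self):
        mask = self.value > 0
        return self._make(self.value * mask, (self,), lambda g: (g * mask,))

    def sigmoid(self):
        y = 1.0 / (1.0 + np.exp(-self.value))
        return self._make(y, (self,), lambda g: (g * y * (1.0 - y),))

    def log(self):
        return self._make(np.log(self.value), (self,),
                          lambda g: (g / self.value,))

    def square(self):
        return self * self

    def clip(self, lo: float, hi: float):
        """Clip values; gradient passes only through the un-clipped region."""
        mask = (self.value >= lo) & (self.value <= hi)
        return self._make(np.clip(self.value, lo, hi), (self,),
                          lambda g: (g * mask,))

    # -- reductions ------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out_val = self.value.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            return (np.broadcast_to(g, self.value.shape).copy(),)

        return self._make(out_val, (self,), backward)

    def mean(self, axis=None, keepdims=False):
        n = (self.value.size if axis is None
             else self.value.shape[axis])
        return self.sum(axis=axis, keepdims=keepdims) / n

    def softmax(self, axis=-1):
        x = self.value
        z = x - x.max(axis=axis, keepdims=True)
        e = np.exp(z)
        y = e / e.sum(axis=axis, keepdims=True)

        def backward(g):
            dot = (g * y).sum(axis=axis, keepdims=True)
            return (y * (g - dot),)

        return self._make(y, (self,), backward)

    # -- backprop driver -------------------------------------------------
    def backward(self):
        """Accumulate gradients of `self` (a scalar) into every leaf with
        requires_grad."""
        if self.value.size != 1:
            raise ValueError("backward() requires a scalar loss")
        order: list[Tensor] = []
        seen: set[int] = set()

        def topo(node: Tensor):
            if id(node) in seen or not node.requires_grad:
                return
            seen.add(id(node))
            for p in node._parents:
                topo(p)
            order.append(node)

        topo(self)
        grads: dict[int, np.ndarray] = {
            id(self): np.ones_like(self.value)}
        for node in reversed(order):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node.requires_grad and node._backward is None:
                node.grad = g if node.grad is None else node.grad + g
            if node._backward is None:
                continue
            for parent, pg in zip(node._parents, node._backward(g)):
                if not parent.requires_grad:
                    continue
                key = id(parent)
                grads[key] = pg if key not in grads else grads[key] + pg


def concat(tensors, axis=0):
    """Concatenate tensors along `axis`."""
    tensors = [Tensor._lift(t) for t in tensors]
    values = [t.value for t in tensors]
    out_val = np.concatenate(values, axis=axis)
    sizes = [v.shape[axis] for v in values]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor(out_val, _parents=tuple(tensors), _backward=backward)


def gather_rows(t: Tensor, idx) -> Tensor:
    """Select rows `idx` of a 2-D tensor (with repeat-aware backward)."""
    idx = np.asarray(idx, dtype=np.intp)
    out_val = t.value[idx]

    def backward(g):
        acc = np.zeros_like(t.value)
        np.add.at(acc, idx, g)
        return (acc,)

    return Tensor(out_val, _parents=(t,), _backward=backward)


def grad_reverse(t: Tensor, scale: float = 1.0) -> Tensor:
    """Identity forward; backward multiplies the gradient by -scale.

    Realises the adversarial min-max in a single backward pass: modules
    upstream of this node receive the negated (scaled) discriminator
    gradient.
    """
    return Tensor(t.value, _parents=(t,),
                  _backward=lambda g: (-scale * g,))
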