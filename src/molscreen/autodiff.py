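"""Minimal reverse-mode automatic differentiation over numpy arrays.

Just enough machinery to train the gated-graph / attention model: broadcast
arithmetic, (batched) matmul, the sigmoid/tanh/exp/log nonlinearities,
axis reductions (sum, mean, max) and concatenation. Float64 throughout;
gradients are accumulated by topological-order backpropagation.
"""

from __future__ import annotations

import numpy as np


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("value", "grad", "_parents", "_backward", "requires_grad")

    def __init__(self, value, requires_grad: bool = False, _parents=(), _backward=None):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in _parents)
        self._parents = _parents
        self._backward = _backward

    @property
    def shape(self):
        return self.value.shape

    # -- graph construction helpers -------------------------------------

    @staticmethod
    def _lift(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def _make(self, value, parents, backward) -> "Tensor":
        return Tensor(value, _parents=parents, _backward=backward)

    # -- arithmetic ------------------------------------------------------

    def __add__(self, other):
        other = self._lift(other)

        def backward(grad, out):
            return (
                _unbroadcast(grad, self.shape) if self.requires_grad else None,
                _unbroadcast(grad, other.shape) if other.requires_grad else None,
            )

        return self._make(self.value + other.value, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        return self._make(-self.value, (self,), lambda grad, out: (-grad,))

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)

        def backward(grad, out):
            return (
                _unbroadcast(grad * other.value, self.shape) if self.requires_grad else None,
                _unbroadcast(grad * self.value, other.shape) if other.requires_grad else None,
            )

        return self._make(self.value * other.value, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)

        def backward(grad, out):
            return (
                _unbroadcast(grad / other.value, self.shape) if self.requires_grad else None,
                _unbroadcast(-grad * self.value / other.value**2, other.shape)
                if other.requires_grad else None,
            )

        return self._make(self.value / other.value, (self, other), backward)

    def __rtruediv__(self, other):
        return self._lift(other) / self

    def __pow__(self, exponent: float):
        def backward(grad, out):
            return (grad * exponent * self.value ** (exponent - 1),)

        return self._make(self.value**exponent, (self,), backward)

    def __matmul__(self, other):
        other = self._lift(other)

        def backward(grad, out):
            a, b = self.value, other.value
            if a.ndim == 1 and b.ndim == 1:
                return (grad * b if self.requires_grad else None,
                        grad * a if other.requires_grad else None)
            ga = gb = None
            if self.requires_grad:
                ga = grad @ np.swapaxes(b, -1, -2) if b.ndim > 1 else np.outer(grad, b)
                ga = _unbroadcast(ga, self.shape)
            if other.requires_grad:
                gb = np.swapaxes(a, -1, -2) @ grad if a.ndim > 1 else np.outer(a, grad)
                gb = _unbroadcast(gb, other.shape)
            return ga, gb

        return self._make(self.value @ other.value, (self, other), backward)

    # -- nonlinearities --------------------------------------------------

    def sigmoid(self):
        with np.errstate(over="ignore"):  # exp overflow saturates to 0/1
            out_val = 1.0 / (1.0 + np.exp(-self.value))

        def backward(grad, out):
            return (grad * out.value * (1.0 - out.value),)

        return self._make(out_val, (self,), backward)

    def tanh(self):
        out_val = np.tanh(self.value)

        def backward(grad, out):
            return (grad * (1.0 - out.value**2),)

        return self._make(out_val, (self,), backward)

    def exp(self):
        out_val = np.exp(self.value)

        def backward(grad, out):
            return (grad * out.value,)

        return self._make(out_val, (self,), backward)

    def log(self):
        def backward(grad, out):
            return (grad / self.value,)

        return self._make(np.log(self.value), (self,), backward)

    # -- reductions & shaping -------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        def backward(grad, out):
            g = np.asarray(grad)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            return (np.broadcast_to(g, self.shape).copy(),)

        return self._make(self.value.sum(axis=axis, keepdims=keepdims), (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        count = self.value.size if axis is None else self.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) / float(count)

    def max(self, axis: int):
        """Max along one axis; ties route the gradient to the first argmax."""
        out_val = self.value.max(axis=axis)
        argmax = self.value.argmax(axis=axis)

        def backward(grad, out):
            g = np.zeros_like(self.value)
            idx = list(np.indices(out_val.shape))
            idx.insert(axis if axis >= 0 else self.value.ndim + axis, argmax)
            g[tuple(idx)] = grad
            return (g,)

        return self._make(out_val, (self,), backward)

    def reshape(self, *shape):
        def backward(grad, out):
            return (grad.reshape(self.shape),)

        return self._make(self.value.reshape(*shape), (self,), backward)

    def softmax(self, axis: int = -1):
        shifted = self - Tensor(self.value.max(axis=axis, keepdims=True))
        e = shifted.exp()
        return e / e.sum(axis=axis, keepdims=True)

    # -- autodiff driver -------------------------------------------------

    def backward(self):
        if self.value.size != 1:
            raise ValueError("backward() requires a scalar output")
        order: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                order.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for parent in node._parents:
                if parent.requires_grad:
                    stack.append((parent, False))
        self.grad = np.ones_like(self.value)
        for node in reversed(order):
            if node._backward is None or node.grad is None:
                continue
            grads = node._backward(node.grad, node)
            for parent, g in zip(node._parents, grads):
                if g is None or not parent.requires_grad:
                    continue
                if parent.grad is None:
                    parent.grad = np.zeros_like(parent.value)
                parent.grad = parent.grad + g


def gather_rows(tensor: Tensor, index: np.ndarray) -> Tensor:
    """Fancy-index rows along axis 0; duplicates accumulate gradient."""
    index = np.asarray(index)

    def backward(grad, out):
        g = np.zeros_like(tensor.value)
        np.add.at(g, index, grad)
        return (g,)

    return Tensor(tensor.value[index], _parents=(tensor,), _backward=backward)


def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(grad, out):
        slicer = [slice(None)] * grad.ndim
        pieces = []
        for k in range(len(tensors)):
            slicer[axis] = slice(offsets[k], offsets[k + 1])
            pieces.append(grad[tuple(slicer)])
        return tuple(pieces)

    return Tensor(
        np.concatenate([t.value for t in tensors], axis=axis),
        _parents=tuple(tensors),
        _backward=backward,
    )


def parameter(value, rng: np.random.Generator | None = None, scale: float | None = None) -> Tensor:
    """A trainable tensor; optionally Glorot-style random initialization."""
    if rng is not None:
        value = np.asarray(value)
        if scale is None:
            fan = sum(value.shape) if value.ndim else 1
            scale = np.sqrt(2.0 / max(fan, 1))
        value = rng.normal(0.0, scale, size=value.shape)
    return Tensor(value, requires_grad=True)


class Adam:
    """Adam optimizer over a flat list of parameter tensors."""

    def __init__(self, params: list[Tensor], lr: float = 0.01,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.weight_decay = weight_decay
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for k, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay and p.value.ndim >= 2:  # matrices only, not biases
                g = g + self.weight_decay * p.value
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g**2
            m_hat = self.m[k] / (1 - self.beta1**self.t)
            v_hat = self.v[k] / (1 - self.beta2**self.t)
            p.value = p.value - self.lr * m_hat / (np.sqrt(v_hat) + self.eps)
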