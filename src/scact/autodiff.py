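"""Minimal reverse-mode automatic differentiation on numpy arrays.

The model components in this package are small multilayer perceptrons with
block-structured (chromosome-masked) first layers, trained with composite
adversarial objectives and later differentiated with respect to their *inputs*
for integrated-gradients attribution.  Both uses need reverse-mode gradients
through arbitrary compositions of matrix products and pointwise nonlinearities,
which this module provides: a :class:`Tensor` wrapping an ``ndarray``, the
operations the model needs, topological-sort backpropagation, and an Adam
optimizer.  Gradient correctness is asserted against central finite differences
in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Adam", "sigmoid", "relu", "concat"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape`, inverting numpy broadcasting."""
    if grad.shape == shape:
        return grad
    # sum leading broadcast axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A node in the computation graph.

    Parameters with ``requires_grad=True`` accumulate ``.grad`` on
    :meth:`backward`.  Operations build the graph lazily; no graph is retained
    between calls unless tensors are reused.
    """

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    # make `ndarray op Tensor` defer to the reflected Tensor operators
    __array_ufunc__ = None

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad)
        self.grad = None
        self._backward = None
        self._parents: tuple = ()

    # ---- graph plumbing -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    @staticmethod
    def _make(data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def backward(self, grad=None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen = set()

        def visit(t: Tensor):
            stack = [(t, False)]
            while stack:
                node, done = stack.pop()
                if done:
                    topo.append(node)
                    continue
                if id(node) in seen or not node.requires_grad:
                    continue
                seen.add(id(node))
                stack.append((node, True))
                for p in node._parents:
                    stack.append((p, False))

        visit(self)
        grads = {id(self): np.asarray(grad, dtype=np.float64)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node._backward is None:
                node.grad = g if node.grad is None else node.grad + g
                continue
            for parent, pg in zip(node._parents, node._backward(g)):
                if not parent.requires_grad or pg is None:
                    continue
                pg = _unbroadcast(pg, parent.data.shape)
                if id(parent) in grads:
                    grads[id(parent)] = grads[id(parent)] + pg
                else:
                    grads[id(parent)] = pg

    def zero_grad(self) -> None:
        self.grad = None

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    # ---- arithmetic -----------------------------------------------------
    def __add__(self, other):
        other = self._wrap(other)
        return self._make(self.data + other.data, (self, other),
                          lambda g: (g, g))

    __radd__ = __add__

    def __neg__(self):
        return self._make(-self.data, (self,), lambda g: (-g,))

    def __sub__(self, other):
        other = self._wrap(other)
        return self._make(self.data - other.data, (self, other),
                          lambda g: (g, -g))

    def __rsub__(self, other):
        return self._wrap(other) - self

    def __mul__(self, other):
        other = self._wrap(other)
        a, b = self.data, other.data
        return self._make(a * b, (self, other),
                          lambda g: (g * b, g * a))

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._wrap(other)
        a, b = self.data, other.data
        return self._make(a / b, (self, other),
                          lambda g: (g / b, -g * a / (b * b)))

    def __rtruediv__(self, other):
        return self._wrap(other) / self

    def __pow__(self, exponent: float):
        a = self.data
        return self._make(a ** exponent, (self,),
                          lambda g: (g * exponent * a ** (exponent - 1),))

    def __matmul__(self, other):
        other = self._wrap(other)
        a, b = self.data, other.data
        return self._make(a @ b, (self, other),
                          lambda g: (g @ b.T, a.T @ g))

    def __getitem__(self, idx):
        def back(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            return (full,)
        return self._make(self.data[idx], (self,), back)

    # ---- reductions & pointwise ----------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        def back(g):
            if axis is None:
                return (np.broadcast_to(g, self.data.shape).copy(),)
            gg = g if keepdims else np.expand_dims(g, axis)
            return (np.broadcast_to(gg, self.data.shape).copy(),)
        return self._make(self.data.sum(axis=axis, keepdims=keepdims),
                          (self,), back)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def log(self):
        a = self.data
        return self._make(np.log(a), (self,), lambda g: (g / a,))

    def exp(self):
        out = np.exp(self.data)
        return self._make(out, (self,), lambda g: (g * out,))

    def clip(self, lo: float, hi: float):
        """Clamp values; gradient passes through only inside the interval."""
        a = self.data
        mask = (a > lo) & (a < hi)
        return self._make(np.clip(a, lo, hi), (self,),
                          lambda g: (g * mask,))


def sigmoid(t: Tensor) -> Tensor:
    out = 1.0 / (1.0 + np.exp(-t.data))
    return Tensor._make(out, (t,), lambda g: (g * out * (1.0 - out),))


def relu(t: Tensor) -> Tensor:
    mask = t.data > 0
    return Tensor._make(t.data * mask, (t,), lambda g: (g * mask,))


def concat(tensors: list, axis: int = 1) -> Tensor:
    datas = [t.data for t in tensors]
    sizes = [d.shape[axis] for d in datas]
    splits = np.cumsum(sizes)[:-1]

    def back(g):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor._make(np.concatenate(datas, axis=axis), tuple(tensors), back)


class Adam:
    """Adam optimizer over a list of parameter tensors (β1=0.9, β2=0.999)."""

    def __init__(self, params: list, lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self._m[i] = self.b1 * self._m[i] + (1 - self.b1) * g
            self._v[i] = self.b2 * self._v[i] + (1 - self.b2) * g * g
            mhat = self._m[i] / (1 - self.b1 ** self.t)
            vhat = self._v[i] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
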