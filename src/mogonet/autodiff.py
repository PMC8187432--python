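"""A small reverse-mode automatic-differentiation engine on numpy arrays.

Supports exactly the operations the models here need: matrix products,
broadcasting add/multiply, reshape, leaky rectifier, row-wise log-softmax,
gathering one entry per row, and reductions.  Gradients are accumulated by
a topological backward sweep; correctness is checked against central finite
differences in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Adam", "leaky_relu", "log_softmax", "softmax", "gather_rows"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum a gradient over the axes that numpy broadcasting expanded."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, size in enumerate(shape):
        if size == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """An ndarray with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=float)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents = parents
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    # -- graph construction helpers -------------------------------------
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def _make(self, data, parents, backward) -> "Tensor":
        req = any(p.requires_grad for p in parents)
        return Tensor(data, requires_grad=req, parents=parents if req else (), backward=backward if req else None)

    # -- operations ------------------------------------------------------
    def __add__(self, other):
        other = self._lift(other)
        out_data = self.data + other.data

        def backward(g):
            return (_unbroadcast(g, self.shape), _unbroadcast(g, other.shape))

        return self._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __mul__(self, other):
        other = self._lift(other)
        out_data = self.data * other.data
        a, b = self.data, other.data

        def backward(g):
            return (_unbroadcast(g * b, self.shape), _unbroadcast(g * a, other.shape))

        return self._make(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __matmul__(self, other):
        other = self._lift(other)
        out_data = self.data @ other.data
        a, b = self.data, other.data

        def backward(g):
            ga = g @ np.swapaxes(b, -1, -2)
            gb = np.swapaxes(a, -1, -2) @ g
            return (_unbroadcast(ga, self.shape), _unbroadcast(gb, other.shape))

        return self._make(out_data, (self, other), backward)

    def reshape(self, *shape):
        old = self.shape

        def backward(g):
            return (g.reshape(old),)

        return self._make(self.data.reshape(*shape), (self,), backward)

    def sum(self):
        def backward(g):
            return (np.broadcast_to(g, self.shape).copy(),)

        return self._make(self.data.sum(), (self,), backward)

    def exp(self):
        out_data = np.exp(self.data)

        def backward(g):
            return (g * out_data,)

        return self._make(out_data, (self,), backward)

    def mean(self):
        n = self.data.size

        def backward(g):
            return (np.broadcast_to(g / n, self.shape).copy(),)

        return self._make(self.data.mean(), (self,), backward)

    # -- backward sweep ---------------------------------------------------
    def backward(self) -> None:
        if self.data.ndim != 0:
            raise ValueError("backward() expects a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()

        def visit(t: Tensor):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        for t in topo:
            t.grad = np.zeros_like(t.data)
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is None:
                continue
            grads = t._backward(t.grad)
            for p, g in zip(t._parents, grads):
                if p.requires_grad:
                    p.grad = p.grad + g if p.grad is not None else g


def leaky_relu(x: Tensor, slope: float = 0.25) -> Tensor:
    mask = np.where(x.data > 0, 1.0, slope)

    def backward(g):
        return (g * mask,)

    return x._make(x.data * mask, (x,), backward)


def log_softmax(x: Tensor) -> Tensor:
    """Row-wise log-softmax of a 2-D logits tensor (numerically shifted)."""
    z = x.data - x.data.max(axis=-1, keepdims=True)
    logsumexp = np.log(np.exp(z).sum(axis=-1, keepdims=True))
    out_data = z - logsumexp
    softmax = np.exp(out_data)

    def backward(g):
        return (g - softmax * g.sum(axis=-1, keepdims=True),)

    return x._make(out_data, (x,), backward)


def softmax(x: np.ndarray) -> np.ndarray:
    """Plain row-wise softmax on an ndarray (no gradient)."""
    z = x - x.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def gather_rows(x: Tensor, index: np.ndarray) -> Tensor:
    """Pick entry ``index[i]`` from row ``i`` of a 2-D tensor."""
    rows = np.arange(x.data.shape[0])

    def backward(g):
        full = np.zeros_like(x.data)
        full[rows, index] = g
        return (full,)

    return x._make(x.data[rows, index], (x,), backward)


class Adam:
    """Adaptive-moment full-batch gradient descent over a set of parameters."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            m_hat = self.m[i] / (1 - self.b1 ** self.t)
            v_hat = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
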