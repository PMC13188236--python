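"""A compact reverse-mode automatic-differentiation engine on numpy arrays.

Every trainable component of the model (feature projections, the
residual GraphSAGE layers, the fusion gates, the prediction head and the
joint objective) is expressed with the :class:`Tensor` wrapper below,
which records the computation graph and back-propagates exact gradients.
The engine supports the operations that the model needs — matrix
multiplication, broadcast arithmetic, concatenation, row gathering,
ELU/ReLU/sigmoid nonlinearities, reductions and clipping — and nothing
else.  Gradients accumulate lazily (no allocation for single-consumer
nodes) and are verified against central finite differences in the test
suite.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "tensor", "concat", "relu", "elu", "sigmoid", "Adam",
           "glorot", "uniform_init"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=float)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad) or any(p.requires_grad for p in parents)
        self._parents = parents
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    def _acc(self, g: np.ndarray) -> None:
        """Accumulate a gradient contribution (out-of-place, alias-safe)."""
        self.grad = g if self.grad is None else self.grad + g

    # -- graph bookkeeping -------------------------------------------------

    def backward(self, grad: np.ndarray | None = None) -> None:
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
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
        for node in topo:
            node.grad = None
        self.grad = np.ones_like(self.data) if grad is None \
            else np.asarray(grad, dtype=float)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_grad(self) -> None:
        self.grad = None

    # -- arithmetic ---------------------------------------------------------

    def _coerce(self, other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other):
        other = self._coerce(other)
        out = Tensor(self.data + other.data, parents=(self, other))

        def bw(g):
            if self.requires_grad:
                self._acc(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._acc(_unbroadcast(g, other.data.shape))
        out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, parents=(self,))

        def bw(g):
            if self.requires_grad:
                self._acc(-g)
        out._backward = bw
        return out

    def __sub__(self, other):
        return self + (-self._coerce(other))

    def __rsub__(self, other):
        return self._coerce(other) + (-self)

    def __mul__(self, other):
        other = self._coerce(other)
        out = Tensor(self.data * other.data, parents=(self, other))

        def bw(g):
            if self.requires_grad:
                self._acc(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._acc(_unbroadcast(g * self.data, other.data.shape))
        out._backward = bw
        return out

    __rmul__ = __mul__

    def __pow__(self, p: float):
        out = Tensor(self.data ** p, parents=(self,))

        def bw(g):
            if self.requires_grad:
                self._acc(g * p * self.data ** (p - 1))
        out._backward = bw
        return out

    def __matmul__(self, other):
        other = self._coerce(other)
        a, b = self.data, other.data
        out = Tensor(a @ b, parents=(self, other))

        def bw(g):
            if self.requires_grad:
                if a.ndim == 1 and b.ndim == 1:
                    self._acc(g * b)
                elif b.ndim == 1 and a.ndim == 2:
                    self._acc(np.outer(g, b))
                else:
                    self._acc(g @ b.T)
            if other.requires_grad:
                if a.ndim == 1 and b.ndim == 1:
                    other._acc(g * a)
                elif a.ndim == 1 and b.ndim == 2:
                    other._acc(np.outer(a, g))
                else:
                    other._acc(a.T @ g)
        out._backward = bw
        return out

    # -- shaping ------------------------------------------------------------

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], parents=(self,))

        def bw(g):
            if self.requires_grad:
                scatter = np.zeros_like(self.data)
                np.add.at(scatter, idx, g)
                self._acc(scatter)
        out._backward = bw
        return out

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), parents=(self,))

        def bw(g):
            if self.requires_grad:
                self._acc(g.reshape(self.data.shape))
        out._backward = bw
        return out

    # -- reductions ---------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), parents=(self,))

        def bw(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._acc(np.broadcast_to(g, self.data.shape))
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                self._acc(np.broadcast_to(gg, self.data.shape))
        out._backward = bw
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- elementwise nonlinearities ------------------------------------------

    def log(self):
        out = Tensor(np.log(self.data), parents=(self,))

        def bw(g):
            if self.requires_grad:
                self._acc(g / self.data)
        out._backward = bw
        return out

    def exp(self):
        out = Tensor(np.exp(self.data), parents=(self,))

        def bw(g):
            if self.requires_grad:
                self._acc(g * out.data)
        out._backward = bw
        return out

    def clip(self, lo: float, hi: float):
        """Clip values; gradient passes only through unclipped entries."""
        out = Tensor(np.clip(self.data, lo, hi), parents=(self,))
        mask = (self.data > lo) & (self.data < hi)

        def bw(g):
            if self.requires_grad:
                self._acc(g * mask)
        out._backward = bw
        return out


def tensor(data, requires_grad: bool = False) -> Tensor:
    return Tensor(data, requires_grad=requires_grad)


def relu(x: Tensor) -> Tensor:
    out = Tensor(np.maximum(x.data, 0.0), parents=(x,))

    def bw(g):
        if x.requires_grad:
            x._acc(g * (x.data > 0))
    out._backward = bw
    return out


def elu(x: Tensor, alpha: float = 1.0) -> Tensor:
    y = np.where(x.data > 0, x.data, alpha * (np.exp(np.minimum(x.data, 0.0)) - 1.0))
    out = Tensor(y, parents=(x,))

    def bw(g):
        if x.requires_grad:
            x._acc(g * np.where(x.data > 0, 1.0, y + alpha))
    out._backward = bw
    return out


def sigmoid(x: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-x.data))
    out = Tensor(s, parents=(x,))

    def bw(g):
        if x.requires_grad:
            x._acc(g * s * (1.0 - s))
    out._backward = bw
    return out


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                 parents=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._acc(g[tuple(sl)])
    out._backward = bw
    return out


# ---------------------------------------------------------------------------
# Parameter initialisation and optimisation
# ---------------------------------------------------------------------------

def uniform_init(rng: np.random.Generator, in_dim: int, out_dim: int) -> Tensor:
    """Uniform ``[-1/sqrt(in_dim), 1/sqrt(in_dim)]`` trainable matrix."""
    bound = 1.0 / np.sqrt(in_dim)
    return Tensor(rng.uniform(-bound, bound, size=(in_dim, out_dim)),
                  requires_grad=True)


def glorot(rng: np.random.Generator, in_dim: int, out_dim: int) -> Tensor:
    bound = np.sqrt(6.0 / (in_dim + out_dim))
    return Tensor(rng.uniform(-bound, bound, size=(in_dim, out_dim)),
                  requires_grad=True)


class Adam:
    """Adam with classic L2 weight decay added to the gradient."""

    def __init__(self, params: list[Tensor], lr: float = 1e-4,
                 betas=(0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad + self.weight_decay * p.data
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
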