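"""Minimal reverse-mode automatic differentiation over numpy arrays.

The montage generator network is tiny (a few dense layers) but its loss is a
composition of the lead-field superposition, the piecewise-linear safety
normalization, the beat-modulation formula and three ratio metrics.  All of
these are built from a small set of primitives, so a compact vectorised tape
suffices.  Piecewise-linear primitives (``abs``, ``relu``, ``max``) use the
standard subgradient at their kink; the kink set has measure zero along a
training trajectory.

Only what the package needs is implemented: elementwise arithmetic with numpy
broadcasting, matrix-vector/matrix products, reductions, indexing,
concatenation, ``exp``/``log``/``sqrt``/``sigmoid``, and ReLU.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "Adam"]


def _as_array(x) -> np.ndarray:
    return np.asarray(x, dtype=np.float64)


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A node in the computation graph holding a float64 array."""

    __slots__ = ("value", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, value, requires_grad: bool = False,
                 parents: tuple = (), backward=None):
        self.value = _as_array(value)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad) or any(
            p.requires_grad for p in parents)
        self._parents = parents
        self._backward = backward

    # -- graph plumbing ---------------------------------------------------

    @property
    def shape(self):
        return self.value.shape

    def item(self) -> float:
        return float(self.value)

    def backward(self) -> None:
        """Accumulate gradients of ``self`` (must be scalar) into leaves."""
        if self.value.size != 1:
            raise ValueError("backward() requires a scalar output")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, iter(self._parents))]
        seen.add(id(self))
        while stack:
            node, it = stack[-1]
            advanced = False
            for p in it:
                if id(p) not in seen and p.requires_grad:
                    seen.add(id(p))
                    stack.append((p, iter(p._parents)))
                    advanced = True
                    break
            if not advanced:
                topo.append(node)
                stack.pop()
        for node in topo:
            node.grad = np.zeros_like(node.value)
        self.grad = np.ones_like(self.value)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    # -- helpers ----------------------------------------------------------

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def _accum(self, g: np.ndarray) -> None:
        if self.requires_grad and self.grad is not None:
            self.grad += _unbroadcast(g, self.value.shape)

    # -- arithmetic -------------------------------------------------------

    def __add__(self, other):
        other = self._lift(other)
        out = Tensor(self.value + other.value, parents=(self, other))
        out._backward = lambda g: (self._accum(g), other._accum(g))
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.value, parents=(self,))
        out._backward = lambda g: self._accum(-g)
        return out

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out = Tensor(self.value * other.value, parents=(self, other))
        out._backward = lambda g: (self._accum(g * other.value),
                                   other._accum(g * self.value))
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        out = Tensor(self.value / other.value, parents=(self, other))

        def bwd(g):
            self._accum(g / other.value)
            other._accum(-g * self.value / other.value ** 2)

        out._backward = bwd
        return out

    def __rtruediv__(self, other):
        return self._lift(other) / self

    def __matmul__(self, other):
        other = self._lift(other)
        out = Tensor(self.value @ other.value, parents=(self, other))
        a, b = self.value, other.value

        def bwd(g):
            if a.ndim == 2 and b.ndim == 1:
                self._accum(np.outer(g, b))
                other._accum(a.T @ g)
            elif a.ndim == 1 and b.ndim == 2:
                self._accum(g @ b.T)
                other._accum(np.outer(a, g))
            elif a.ndim == 2 and b.ndim == 2:
                self._accum(g @ b.T)
                other._accum(a.T @ g)
            else:  # 1-D dot product
                self._accum(g * b)
                other._accum(g * a)

        out._backward = bwd
        return out

    def reshape(self, shape):
        out = Tensor(self.value.reshape(shape), parents=(self,))
        out._backward = lambda g: self._accum(g.reshape(self.value.shape))
        return out

    def __getitem__(self, idx):
        out = Tensor(self.value[idx], parents=(self,))

        def bwd(g):
            if self.requires_grad and self.grad is not None:
                np.add.at(self.grad, idx, g)

        out._backward = bwd
        return out

    # -- nonlinearities ---------------------------------------------------

    def relu(self):
        mask = self.value > 0
        out = Tensor(np.where(mask, self.value, 0.0), parents=(self,))
        out._backward = lambda g: self._accum(g * mask)
        return out

    def abs(self):
        sign = np.sign(self.value)  # subgradient 0 at the kink
        out = Tensor(np.abs(self.value), parents=(self,))
        out._backward = lambda g: self._accum(g * sign)
        return out

    def exp(self):
        val = np.exp(self.value)
        out = Tensor(val, parents=(self,))
        out._backward = lambda g: self._accum(g * val)
        return out

    def log(self):
        out = Tensor(np.log(self.value), parents=(self,))
        out._backward = lambda g: self._accum(g / self.value)
        return out

    def sqrt(self):
        val = np.sqrt(self.value)
        out = Tensor(val, parents=(self,))
        out._backward = lambda g: self._accum(g / (2.0 * val))
        return out

    def sigmoid(self):
        v = self.value
        # numerically stable logistic
        val = np.empty_like(v)
        pos = v >= 0
        val[pos] = 1.0 / (1.0 + np.exp(-v[pos]))
        ev = np.exp(v[~pos])
        val[~pos] = ev / (1.0 + ev)
        out = Tensor(val, parents=(self,))
        out._backward = lambda g: self._accum(g * val * (1.0 - val))
        return out

    # -- reductions -------------------------------------------------------

    def sum(self):
        out = Tensor(self.value.sum(), parents=(self,))
        out._backward = lambda g: self._accum(np.broadcast_to(g, self.value.shape))
        return out

    def mean(self):
        n = self.value.size
        out = Tensor(self.value.mean(), parents=(self,))
        out._backward = lambda g: self._accum(np.broadcast_to(g / n, self.value.shape))
        return out

    def max(self):
        """Max over all elements; subgradient routed to the first argmax."""
        idx = np.unravel_index(np.argmax(self.value), self.value.shape)
        out = Tensor(self.value[idx], parents=(self,))

        def bwd(g):
            if self.requires_grad and self.grad is not None:
                self.grad[idx] += g

        out._backward = bwd
        return out


def concat(tensors: list[Tensor]) -> Tensor:
    """Concatenate 1-D tensors."""
    tensors = [Tensor._lift(t) for t in tensors]
    out = Tensor(np.concatenate([t.value for t in tensors]),
                 parents=tuple(tensors))
    sizes = [t.value.size for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            t._accum(g[a:b])

    out._backward = bwd
    return out


class Adam:
    """Adam gradient-descent optimizer on a list of parameter tensors."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self._m = [np.zeros_like(p.value) for p in params]
        self._v = [np.zeros_like(p.value) for p in params]
        self._t = 0

    def step(self) -> None:
        self._t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self._m, self._v):
            g = p.grad
            if g is None:
                continue
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1 ** self._t)
            vhat = v / (1 - b2 ** self._t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
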