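"""Minimal reverse-mode automatic differentiation over numpy arrays.

The encoder-decoder model in this package is small (dense graphs with at
most a few thousand nodes) and full-batch, so a tape-based tensor engine
with the handful of primitives the model needs — matmul, broadcasting
add/mul, the GAT/GCN nonlinearities, masked row-softmax, gather — is all
that is required.  Gradients of every primitive are checked against central
finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "Adam"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape`, inverting numpy broadcasting."""
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
    """A numpy array with a gradient tape."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # -- construction helpers -------------------------------------------------

    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    @classmethod
    def _from_op(cls, data, parents, backward) -> "Tensor":
        out = cls(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- arithmetic -----------------------------------------------------------

    def __add__(self, other):
        other = self._wrap(other)
        out_data = self.data + other.data

        def backward(g):
            return (_unbroadcast(g, self.data.shape),
                    _unbroadcast(g, other.data.shape))

        return self._from_op(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        return self._from_op(-self.data, (self,), lambda g: (-g,))

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)
        out_data = self.data * other.data

        def backward(g):
            return (_unbroadcast(g * other.data, self.data.shape),
                    _unbroadcast(g * self.data, other.data.shape))

        return self._from_op(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, scalar):
        if isinstance(scalar, Tensor):
            raise TypeError("division only supported by python scalars")
        return self * (1.0 / scalar)

    def __matmul__(self, other):
        other = self._wrap(other)
        out_data = self.data @ other.data

        def backward(g):
            return (g @ other.data.T, self.data.T @ g)

        return self._from_op(out_data, (self, other), backward)

    @property
    def T(self):
        return self._from_op(self.data.T, (self,), lambda g: (g.T,))

    # -- nonlinearities -------------------------------------------------------

    def relu(self):
        mask = self.data > 0
        return self._from_op(self.data * mask, (self,), lambda g: (g * mask,))

    def leaky_relu(self, slope: float = 0.2):
        factor = np.where(self.data > 0, 1.0, slope)
        return self._from_op(self.data * factor, (self,), lambda g: (g * factor,))

    def elu(self, alpha: float = 1.0):
        neg = alpha * (np.exp(np.minimum(self.data, 0.0)) - 1.0)
        out_data = np.where(self.data > 0, self.data, neg)
        deriv = np.where(self.data > 0, 1.0, neg + alpha)
        return self._from_op(out_data, (self,), lambda g: (g * deriv,))

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-self.data))
        return self._from_op(s, (self,), lambda g: (g * s * (1.0 - s),))

    def exp(self):
        e = np.exp(self.data)
        return self._from_op(e, (self,), lambda g: (g * e,))

    def log(self):
        return self._from_op(np.log(self.data), (self,), lambda g: (g / self.data,))

    def clip(self, lo: float, hi: float):
        """Clamp values; gradient passes through only inside [lo, hi]."""
        inside = (self.data >= lo) & (self.data <= hi)
        return self._from_op(np.clip(self.data, lo, hi), (self,),
                             lambda g: (g * inside,))

    def row_softmax(self, mask: np.ndarray | None = None):
        """Numerically stable softmax over the last axis.

        With `mask` (boolean, same shape), the normalization runs over the
        True entries of each row only and masked-out entries get weight 0;
        every row must have at least one True entry.
        """
        z = self.data
        if mask is not None:
            if not mask.any(axis=-1).all():
                raise ValueError("row_softmax: a row has an empty neighborhood")
            z = np.where(mask, z, -np.inf)
        z = z - z.max(axis=-1, keepdims=True)
        e = np.exp(z)
        p = e / e.sum(axis=-1, keepdims=True)

        def backward(g):
            gp = g * p
            return (gp - p * gp.sum(axis=-1, keepdims=True),)

        return self._from_op(p, (self,), backward)

    # -- reductions / reshaping ----------------------------------------------

    def __getitem__(self, key):
        out_data = self.data[key]

        def backward(g):
            grad = np.zeros_like(self.data)
            grad[key] += g
            return (grad,)

        return self._from_op(out_data, (self,), backward)

    def reshape(self, shape):
        old = self.data.shape
        return self._from_op(self.data.reshape(shape), (self,),
                             lambda g: (g.reshape(old),))

    def sum(self):
        def backward(g):
            return (np.broadcast_to(g, self.data.shape).copy(),)
        return self._from_op(self.data.sum(), (self,), backward)

    def mean(self):
        n = self.data.size
        def backward(g):
            return (np.broadcast_to(g / n, self.data.shape).copy(),)
        return self._from_op(self.data.mean(), (self,), backward)

    def gather(self, rows: np.ndarray, cols: np.ndarray):
        """Pick entries (rows[i], cols[i]) from a 2-D tensor into a 1-D one."""
        out_data = self.data[rows, cols]

        def backward(g):
            grad = np.zeros_like(self.data)
            np.add.at(grad, (rows, cols), g)
            return (grad,)

        return self._from_op(out_data, (self,), backward)

    # -- backward pass --------------------------------------------------------

    def backward(self):
        if self.data.ndim != 0:
            raise ValueError("backward() requires a scalar tensor")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
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

        for node in topo:
            node.grad = np.zeros_like(node.data)
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is None:
                continue
            grads = node._backward(node.grad)
            for parent, g in zip(node._parents, grads):
                if parent.requires_grad:
                    if parent.grad is None:
                        parent.grad = np.zeros_like(parent.data)
                    parent.grad += g


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    """Concatenate tensors along `axis`."""
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor._from_op(data, tuple(tensors), backward)


class Adam:
    """Adam optimizer over a list of parameter tensors."""

    def __init__(self, params: list[Tensor], lr: float = 1e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            self._m[i] = self.b1 * self._m[i] + (1 - self.b1) * g
            self._v[i] = self.b2 * self._v[i] + (1 - self.b2) * g * g
            m_hat = self._m[i] / (1 - self.b1 ** self.t)
            v_hat = self._v[i] / (1 - self.b2 ** self.t)
            p.data -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None
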