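"""Minimal reverse-mode automatic differentiation on NumPy arrays.

Provides exactly the operations the sequence models in this package need:
broadcasted arithmetic, matrix products, slicing/gather, concatenation,
element-wise nonlinearities and (log-)softmax.  Everything is float64 so
finite-difference gradient checks are meaningful.

Functions such as :func:`sigmoid` and :func:`softmax` dispatch on their
argument type: given a plain ``ndarray`` they return an ``ndarray``, given a
:class:`Tensor` they extend the graph.  This lets the recurrent-cell math be
written once and reused for both the differentiable model and plain NumPy
reference computations.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "parameter",
    "constant",
    "sigmoid",
    "softmax",
    "log_softmax",
    "tanh",
    "exp",
    "log",
    "tsum",
    "concatenate",
    "Adam",
]


def _as_array(x) -> np.ndarray:
    return np.asarray(x, dtype=np.float64)


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (reverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


def _key_is_fancy(key) -> bool:
    if isinstance(key, tuple):
        return any(isinstance(k, (np.ndarray, list)) for k in key)
    return isinstance(key, (np.ndarray, list))


class Tensor:
    """Node in the computation graph wrapping a float64 ndarray."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward", "name")

    # Make `ndarray <op> Tensor` defer to the Tensor reflected operators
    # instead of NumPy broadcasting over a 0-d object array.
    __array_ufunc__ = None

    def __init__(self, data, requires_grad=False, parents=(), backward=None, name=""):
        self.data = _as_array(data)
        self.grad = None
        self.requires_grad = bool(requires_grad) or any(p.requires_grad for p in parents)
        self._parents = parents
        self._backward = backward
        self.name = name

    # -- structural ---------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def T(self):
        out = Tensor(self.data.T, parents=(self,))
        out._backward = lambda g, s=self: _accum(s, g.T)
        return out

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.data.shape
        out = Tensor(self.data.reshape(shape), parents=(self,))
        out._backward = lambda g, s=self, o=old: _accum(s, g.reshape(o))
        return out

    def __getitem__(self, key):
        out = Tensor(self.data[key], parents=(self,))

        def back(g, s=self, k=key):
            full = np.zeros_like(s.data)
            if _key_is_fancy(k):
                np.add.at(full, k, g)
            else:
                full[k] += g
            _accum(s, full)

        out._backward = back
        return out

    def detach(self) -> np.ndarray:
        return self.data

    # -- arithmetic ---------------------------------------------------------
    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor(self.data + other.data, parents=(self, other))

        def back(g, a=self, b=other):
            _accum(a, _unbroadcast(g, a.data.shape))
            _accum(b, _unbroadcast(g, b.data.shape))

        out._backward = back
        return out

    __radd__ = __add__

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor(self.data * other.data, parents=(self, other))

        def back(g, a=self, b=other):
            _accum(a, _unbroadcast(g * b.data, a.data.shape))
            _accum(b, _unbroadcast(g * a.data, b.data.shape))

        out._backward = back
        return out

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-other if isinstance(other, Tensor) else -_as_array(other))

    def __rsub__(self, other):
        return (-self) + other

    def __truediv__(self, other):
        if isinstance(other, Tensor):
            return self * other ** (-1.0)
        return self * (1.0 / _as_array(other))

    def __rtruediv__(self, other):
        return self ** (-1.0) * other

    def __pow__(self, exponent: float):
        out = Tensor(self.data ** exponent, parents=(self,))

        def back(g, a=self, p=exponent):
            _accum(a, g * p * a.data ** (p - 1.0))

        out._backward = back
        return out

    def __matmul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor(self.data @ other.data, parents=(self, other))

        def back(g, a=self, b=other):
            ga = g @ b.data.T if b.data.ndim == 2 else np.outer(g, b.data) if a.data.ndim == 2 else g * b.data
            gb = a.data.T @ g if a.data.ndim == 2 else np.outer(a.data, g) if b.data.ndim == 2 else g * a.data
            _accum(a, ga.reshape(a.data.shape))
            _accum(b, gb.reshape(b.data.shape))

        out._backward = back
        return out

    # -- autodiff driver ----------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(node):
            if id(node) in seen:
                return
            seen.add(id(node))
            for p in node._parents:
                visit(p)
            topo.append(node)

        visit(self)
        for node in topo:
            node.grad = None
        self.grad = _as_array(grad)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


def _accum(node: Tensor, grad: np.ndarray):
    if node.grad is None:
        node.grad = np.array(grad, dtype=np.float64)
    else:
        node.grad = node.grad + grad


def parameter(data, name="") -> Tensor:
    return Tensor(data, requires_grad=True, name=name)


def constant(data) -> Tensor:
    return Tensor(data)


# -- dispatching elementwise functions --------------------------------------

def _np_sigmoid(x):
    out = np.empty_like(x, dtype=np.float64)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def sigmoid(x):
    if isinstance(x, Tensor):
        y = _np_sigmoid(x.data)
        out = Tensor(y, parents=(x,))
        out._backward = lambda g, a=x, v=y: _accum(a, g * v * (1.0 - v))
        return out
    return _np_sigmoid(_as_array(x))


def tanh(x):
    if isinstance(x, Tensor):
        y = np.tanh(x.data)
        out = Tensor(y, parents=(x,))
        out._backward = lambda g, a=x, v=y: _accum(a, g * (1.0 - v * v))
        return out
    return np.tanh(_as_array(x))


def exp(x):
    if isinstance(x, Tensor):
        y = np.exp(x.data)
        out = Tensor(y, parents=(x,))
        out._backward = lambda g, a=x, v=y: _accum(a, g * v)
        return out
    return np.exp(_as_array(x))


def log(x):
    if isinstance(x, Tensor):
        out = Tensor(np.log(x.data), parents=(x,))
        out._backward = lambda g, a=x: _accum(a, g / a.data)
        return out
    return np.log(_as_array(x))


def tsum(x, axis=None, keepdims=False):
    """Sum that works on Tensors and ndarrays alike."""
    if isinstance(x, Tensor):
        out = Tensor(x.data.sum(axis=axis, keepdims=keepdims), parents=(x,))

        def back(g, a=x, ax=axis, kd=keepdims):
            if ax is not None and not kd:
                g = np.expand_dims(g, ax)
            _accum(a, np.broadcast_to(g, a.data.shape))

        out._backward = back
        return out
    return _as_array(x).sum(axis=axis, keepdims=keepdims)


def softmax(x, axis=-1):
    if isinstance(x, Tensor):
        shift = x - x.data.max(axis=axis, keepdims=True)
        e = exp(shift)
        return e / tsum(e, axis=axis, keepdims=True)
    x = _as_array(x)
    e = np.exp(x - x.max(axis=axis, keepdims=True))
    return e / e.sum(axis=axis, keepdims=True)


def log_softmax(x, axis=-1):
    if isinstance(x, Tensor):
        shift = x - x.data.max(axis=axis, keepdims=True)
        return shift - log(tsum(exp(shift), axis=axis, keepdims=True))
    x = _as_array(x)
    shift = x - x.max(axis=axis, keepdims=True)
    return shift - np.log(np.exp(shift).sum(axis=axis, keepdims=True))


def concatenate(parts, axis=-1):
    if any(isinstance(p, Tensor) for p in parts):
        parts = [p if isinstance(p, Tensor) else Tensor(p) for p in parts]
        out = Tensor(np.concatenate([p.data for p in parts], axis=axis), parents=tuple(parts))
        sizes = [p.data.shape[axis] for p in parts]

        def back(g, ps=parts, sz=sizes, ax=axis):
            offset = 0
            for p, s in zip(ps, sz):
                sl = [slice(None)] * g.ndim
                sl[ax] = slice(offset, offset + s)
                _accum(p, g[tuple(sl)])
                offset += s

        out._backward = back
        return out
    return np.concatenate([_as_array(p) for p in parts], axis=axis)


class Adam:
    """Standard Adam optimizer over a list of parameter Tensors."""

    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = list(params)
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1 ** self.t)
            vhat = self.v[i] / (1 - b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None
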