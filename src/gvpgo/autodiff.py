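"""Minimal reverse-mode automatic differentiation over numpy arrays.

A small tape-based engine sufficient for the geometric vector perceptron
and transformer layers in this package: broadcasting arithmetic, batched
matmul, reductions, gather/scatter indexing, and the handful of pointwise
nonlinearities the model uses. Gradients are accumulated in float64.

Only what the model needs is implemented; this is not a general framework.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "stack", "index_add", "softmax", "layer_norm", "Adam"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    # make numpy defer to the reflected Tensor operators instead of
    # broadcasting a Tensor as an object scalar
    __array_ufunc__ = None

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=float)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    def _make(self, data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        other = self._lift(other)
        out_data = self.data + other.data

        def backward(g):
            return _unbroadcast(g, self.shape), _unbroadcast(g, other.shape)

        return self._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        return self._make(-self.data, (self,), lambda g: (-g,))

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out_data = self.data * other.data

        def backward(g):
            return (_unbroadcast(g * other.data, self.shape),
                    _unbroadcast(g * self.data, other.shape))

        return self._make(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        out_data = self.data / other.data

        def backward(g):
            return (_unbroadcast(g / other.data, self.shape),
                    _unbroadcast(-g * self.data / other.data**2, other.shape))

        return self._make(out_data, (self, other), backward)

    def __rtruediv__(self, other):
        return self._lift(other) / self

    def __pow__(self, p: float):
        out_data = self.data**p

        def backward(g):
            return (g * p * self.data ** (p - 1),)

        return self._make(out_data, (self,), backward)

    def __matmul__(self, other):
        other = self._lift(other)
        out_data = self.data @ other.data

        def backward(g):
            a, b = self.data, other.data
            if a.ndim == 1 and b.ndim == 1:
                ga, gb = g * b, g * a
            elif a.ndim == 1:
                ga = (b @ g) if b.ndim == 2 else None
                gb = np.outer(a, g)
                if ga is None:
                    raise NotImplementedError
            elif b.ndim == 1:
                ga = np.einsum("...i,j->...ij", g, b) if a.ndim > 2 else np.outer(g, b)
                gb = np.einsum("...ij,...i->j", a, g)
            else:
                ga = g @ np.swapaxes(b, -1, -2)
                gb = np.swapaxes(a, -1, -2) @ g
            return _unbroadcast(ga, self.shape), _unbroadcast(gb, other.shape)

        return self._make(out_data, (self, other), backward)

    # -- pointwise ------------------------------------------------------------
    def exp(self):
        out_data = np.exp(self.data)
        return self._make(out_data, (self,), lambda g: (g * out_data,))

    def log(self):
        return self._make(np.log(self.data), (self,), lambda g: (g / self.data,))

    def sqrt(self):
        out_data = np.sqrt(self.data)
        return self._make(out_data, (self,), lambda g: (g * 0.5 / out_data,))

    def relu(self):
        out_data = np.maximum(self.data, 0.0)
        return self._make(out_data, (self,), lambda g: (g * (self.data > 0),))

    def sigmoid(self):
        out_data = 0.5 * (1.0 + np.tanh(0.5 * self.data))  # numerically stable logistic
        return self._make(out_data, (self,), lambda g: (g * out_data * (1.0 - out_data),))

    def clip(self, lo: float, hi: float):
        out_data = np.clip(self.data, lo, hi)
        inside = (self.data > lo) & (self.data < hi)
        return self._make(out_data, (self,), lambda g: (g * inside,))

    # -- reductions and shaping -----------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            return (np.broadcast_to(g, self.shape).copy(),)

        return self._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        out_data = self.data.reshape(*shape)
        return self._make(out_data, (self,), lambda g: (g.reshape(self.shape),))

    def swapaxes(self, a: int, b: int):
        out_data = np.swapaxes(self.data, a, b)
        return self._make(out_data, (self,), lambda g: (np.swapaxes(g, a, b),))

    @property
    def T(self):
        return self.swapaxes(-1, -2)

    def __getitem__(self, idx):
        out_data = self.data[idx]

        def backward(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            return (full,)

        return self._make(out_data, (self,), backward)

    def norm(self, axis: int = -1, keepdims: bool = False, eps: float = 1e-8):
        """Row-wise L2 norm with an epsilon floor inside the square root."""
        return ((self * self).sum(axis=axis, keepdims=keepdims) + eps).sqrt()

    # -- backward pass ----------------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
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
        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=float)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node._backward is None:
                node.grad = g if node.grad is None else node.grad + g
                continue
            parent_grads = node._backward(g)
            for p, pg in zip(node._parents, parent_grads):
                if not p.requires_grad or pg is None:
                    continue
                if id(p) in grads:
                    grads[id(p)] = grads[id(p)] + pg
                else:
                    grads[id(p)] = pg
            if not node._parents:
                node.grad = g if node.grad is None else node.grad + g
        # leaves reached through grads dict
        # (leaf = requires_grad with no _backward; handled above)


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        return tuple(np.split(g, splits, axis=axis))

    out = Tensor(out_data)
    if any(t.requires_grad for t in tensors):
        out.requires_grad = True
        out._parents = tuple(tensors)
        out._backward = backward
    return out


def stack(tensors: list[Tensor], axis: int = 0) -> Tensor:
    expanded = []
    for t in tensors:
        t = Tensor._lift(t)
        shape = list(t.shape)
        shape.insert(axis if axis >= 0 else t.ndim + 1 + axis, 1)
        expanded.append(t.reshape(*shape))
    return concat(expanded, axis=axis)


def index_add(n: int, index: np.ndarray, values: Tensor) -> Tensor:
    """Scatter-add ``values`` (rows) into ``n`` slots by ``index`` (segment sum)."""
    values = Tensor._lift(values)
    out_shape = (n,) + values.shape[1:]
    out_data = np.zeros(out_shape)
    np.add.at(out_data, index, values.data)

    def backward(g):
        return (g[index],)

    out = Tensor(out_data)
    if values.requires_grad:
        out.requires_grad = True
        out._parents = (values,)
        out._backward = backward
    return out


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    shifted = x - np.max(x.data, axis=axis, keepdims=True)  # constant shift
    e = shifted.exp()
    return e / e.sum(axis=axis, keepdims=True)


def layer_norm(x: Tensor, gain: Tensor, bias: Tensor, eps: float = 1e-5) -> Tensor:
    mu = x.mean(axis=-1, keepdims=True)
    centered = x - mu
    var = (centered * centered).mean(axis=-1, keepdims=True)
    return centered / (var + eps).sqrt() * gain + bias


class Adam:
    """Adam optimizer over a list of parameter Tensors."""

    def __init__(self, params: list[Tensor], lr: float = 1e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def clip_grad_norm(self, max_norm: float) -> float:
        total = np.sqrt(sum(float(np.sum(p.grad**2)) for p in self.params if p.grad is not None))
        if total > max_norm and total > 0:
            scale = max_norm / total
            for p in self.params:
                if p.grad is not None:
                    p.grad = p.grad * scale
        return total

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * p.grad
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * p.grad**2
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)
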