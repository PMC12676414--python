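"""Minimal reverse-mode automatic differentiation on numpy arrays.

A small tape: each :class:`Tensor` wraps an ndarray and records how to push
gradients to its parents; ``backward`` runs the tape in reverse topological
order. Supports exactly the operations the policy networks and PPO losses
need (dense layers, tanh/SiLU/softplus, layer normalization, Gaussian
log-densities, clipped surrogates) — nothing more.

Broadcasting follows numpy; gradients are summed back to the parent shape.
"""

from __future__ import annotations

import numpy as np


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum out broadcast dimensions so grad matches the parent's shape."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "_parents", "_backward", "requires_grad")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=float)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = parents if self.requires_grad else ()
        self._backward = backward if self.requires_grad else None

    # -- helpers -------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @staticmethod
    def _wrap(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def _accum(self, g: np.ndarray) -> None:
        g = _unbroadcast(np.asarray(g, dtype=float), self.data.shape)
        self.grad = g if self.grad is None else self.grad + g

    # -- arithmetic ----------------------------------------------------
    def __add__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data + other.data, parents=(self, other))
        out._backward = lambda g: (self._accum(g), other._accum(g))
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, parents=(self,))
        out._backward = lambda g: self._accum(-g)
        return out

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data * other.data, parents=(self, other))
        out._backward = lambda g: (self._accum(g * other.data), other._accum(g * self.data))
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data / other.data, parents=(self, other))

        def back(g):
            self._accum(g / other.data)
            other._accum(-g * self.data / other.data ** 2)

        out._backward = back
        return out

    def __rtruediv__(self, other):
        return self._wrap(other) / self

    def __matmul__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data @ other.data, parents=(self, other))

        def back(g):
            self._accum(g @ other.data.T)
            other._accum(self.data.T @ g)

        out._backward = back
        return out

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], parents=(self,))

        def back(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            self._accum(full)

        out._backward = back
        return out

    # -- elementwise ---------------------------------------------------
    def square(self):
        return self * self

    def exp(self):
        out = Tensor(np.exp(self.data), parents=(self,))
        out._backward = lambda g: self._accum(g * out.data)
        return out

    def log(self):
        out = Tensor(np.log(self.data), parents=(self,))
        out._backward = lambda g: self._accum(g / self.data)
        return out

    def sqrt(self):
        out = Tensor(np.sqrt(self.data), parents=(self,))
        out._backward = lambda g: self._accum(g * 0.5 / out.data)
        return out

    def tanh(self):
        out = Tensor(np.tanh(self.data), parents=(self,))
        out._backward = lambda g: self._accum(g * (1.0 - out.data ** 2))
        return out

    def sigmoid(self):
        out = Tensor(1.0 / (1.0 + np.exp(-self.data)), parents=(self,))
        out._backward = lambda g: self._accum(g * out.data * (1.0 - out.data))
        return out

    def softplus(self):
        # log(1 + exp(x)), computed stably
        out = Tensor(np.logaddexp(0.0, self.data), parents=(self,))
        out._backward = lambda g: self._accum(g / (1.0 + np.exp(-self.data)))
        return out

    def silu(self):
        s = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(self.data * s, parents=(self,))
        out._backward = lambda g: self._accum(g * (s * (1.0 + self.data * (1.0 - s))))
        return out

    def minimum(self, other):
        other = self._wrap(other)
        mask = self.data <= other.data
        out = Tensor(np.where(mask, self.data, other.data), parents=(self, other))
        out._backward = lambda g: (self._accum(g * mask), other._accum(g * ~mask))
        return out

    def maximum(self, other):
        other = self._wrap(other)
        mask = self.data >= other.data
        out = Tensor(np.where(mask, self.data, other.data), parents=(self, other))
        out._backward = lambda g: (self._accum(g * mask), other._accum(g * ~mask))
        return out

    def clip(self, lo: float, hi: float):
        return self.maximum(Tensor(np.full_like(self.data, lo))).minimum(
            Tensor(np.full_like(self.data, hi))
        )

    # -- reductions / shape --------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), parents=(self,))

        def back(g):
            g = np.asarray(g, dtype=float)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape))

        out._backward = back
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), parents=(self,))
        out._backward = lambda g: self._accum(g.reshape(self.data.shape))
        return out

    # -- graph ---------------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()

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
        self._accum(grad)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    datas = [t.data for t in tensors]
    out = Tensor(np.concatenate(datas, axis=axis), parents=tuple(tensors))
    sizes = [d.shape[axis] for d in datas]
    splits = np.cumsum(sizes)[:-1]

    def back(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            t._accum(piece)

    out._backward = back
    return out


def layer_norm(x: Tensor, eps: float = 1e-6) -> Tensor:
    """Normalize the last axis to zero mean, unit variance (no affine)."""
    mu = x.mean(axis=-1, keepdims=True)
    xc = x - mu
    var = xc.square().mean(axis=-1, keepdims=True)
    return xc / (var + eps).sqrt()


def gaussian_log_prob(x: Tensor | np.ndarray, mean: Tensor, logvar: Tensor) -> Tensor:
    """Diagonal-Gaussian log density, summed over the last axis."""
    x = x if isinstance(x, Tensor) else Tensor(x)
    d = x - mean
    return (-0.5 * (logvar + d.square() * (-logvar).exp() + np.log(2.0 * np.pi))).sum(axis=-1)


def tanh_correction(u: Tensor | np.ndarray) -> Tensor:
    """sum log(1 - tanh(u)^2) via the stable identity 2(log2 - u - softplus(-2u))."""
    u = u if isinstance(u, Tensor) else Tensor(u)
    return (2.0 * (np.log(2.0) - u - (-2.0 * u).softplus())).sum(axis=-1)
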