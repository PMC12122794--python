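"""A small reverse-mode automatic-differentiation engine on NumPy arrays.

Provides the minimal tensor algebra needed by the temporal-attention models in
this package: broadcasting arithmetic, batched matrix products, the usual
pointwise nonlinearities, reductions, indexing and concatenation — each with an
exact vector-Jacobian product. Gradients accumulate into ``Tensor.grad`` for
every node with ``requires_grad`` (including intermediates, which is what
gradient-based saliency needs).
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
from scipy.special import erf

__all__ = ["Tensor", "concatenate", "stack"]

_INV_SQRT2 = float(1.0 / np.sqrt(2.0))       # python floats: no dtype promotion
_INV_SQRT_2PI = float(1.0 / np.sqrt(2.0 * np.pi))


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, n in enumerate(shape) if n == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


def _as_tensor(x) -> "Tensor":
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64))


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False, _prev: tuple = (), _backward=None):
        arr = np.asarray(data)
        if arr.dtype not in (np.float32, np.float64):
            arr = arr.astype(np.float64)
        self.data = arr
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad) or any(p.requires_grad for p in _prev)
        self._prev = _prev
        self._backward = _backward

    # ------------------------------------------------------------------ basic
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    @property
    def size(self) -> int:
        return self.data.size

    def __repr__(self) -> str:  # pragma: no cover
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    def numpy(self) -> np.ndarray:
        return self.data

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    # ------------------------------------------------------------- arithmetic
    def __add__(self, other):
        other = _as_tensor(other)
        out = Tensor(self.data + other.data, _prev=(self, other))

        def _bw(g):
            return _unbroadcast(g, self.shape), _unbroadcast(g, other.shape)

        out._backward = _bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, _prev=(self,))
        out._backward = lambda g: (-g,)
        return out

    def __sub__(self, other):
        return self + (-_as_tensor(other))

    def __rsub__(self, other):
        return _as_tensor(other) + (-self)

    def __mul__(self, other):
        other = _as_tensor(other)
        out = Tensor(self.data * other.data, _prev=(self, other))

        def _bw(g):
            return (
                _unbroadcast(g * other.data, self.shape),
                _unbroadcast(g * self.data, other.shape),
            )

        out._backward = _bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = _as_tensor(other)
        out = Tensor(self.data / other.data, _prev=(self, other))

        def _bw(g):
            return (
                _unbroadcast(g / other.data, self.shape),
                _unbroadcast(-g * self.data / other.data**2, other.shape),
            )

        out._backward = _bw
        return out

    def __rtruediv__(self, other):
        return _as_tensor(other) / self

    def __pow__(self, p: float):
        out = Tensor(self.data**p, _prev=(self,))
        out._backward = lambda g: (g * p * self.data ** (p - 1),)
        return out

    def __matmul__(self, other):
        other = _as_tensor(other)
        out = Tensor(np.matmul(self.data, other.data), _prev=(self, other))

        def _bw(g):
            ga = np.matmul(g, np.swapaxes(other.data, -1, -2))
            gb = np.matmul(np.swapaxes(self.data, -1, -2), g)
            return _unbroadcast(ga, self.shape), _unbroadcast(gb, other.shape)

        out._backward = _bw
        return out

    # -------------------------------------------------------------- pointwise
    def exp(self):
        out = Tensor(np.exp(self.data), _prev=(self,))
        out._backward = lambda g: (g * out.data,)
        return out

    def log(self):
        out = Tensor(np.log(self.data), _prev=(self,))
        out._backward = lambda g: (g / self.data,)
        return out

    def sqrt(self):
        out = Tensor(np.sqrt(self.data), _prev=(self,))
        out._backward = lambda g: (g * 0.5 / out.data,)
        return out

    def tanh(self):
        out = Tensor(np.tanh(self.data), _prev=(self,))
        out._backward = lambda g: (g * (1.0 - out.data**2),)
        return out

    def sigmoid(self):
        out = Tensor(1.0 / (1.0 + np.exp(-self.data)), _prev=(self,))
        out._backward = lambda g: (g * out.data * (1.0 - out.data),)
        return out

    def relu(self):
        out = Tensor(np.maximum(self.data, 0.0), _prev=(self,))
        out._backward = lambda g: (g * (self.data > 0),)
        return out

    def gelu(self):
        """Exact (erf) GELU: x * Phi(x)."""
        phi = 0.5 * (1.0 + erf(self.data * _INV_SQRT2))
        out = Tensor(self.data * phi, _prev=(self,))
        pdf = np.exp(-0.5 * self.data**2) * _INV_SQRT_2PI
        out._backward = lambda g: (g * (phi + self.data * pdf),)
        return out

    def abs(self):
        out = Tensor(np.abs(self.data), _prev=(self,))
        out._backward = lambda g: (g * np.sign(self.data),)
        return out

    # ------------------------------------------------------------- reductions
    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), _prev=(self,))

        def _bw(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            return (np.broadcast_to(g, self.shape).copy(),)

        out._backward = _bw
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.size if axis is None else np.prod(
            [self.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    # --------------------------------------------------- softmax / logsoftmax
    def softmax(self, axis: int = -1):
        shifted = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(shifted)
        s = e / e.sum(axis=axis, keepdims=True)
        out = Tensor(s, _prev=(self,))

        def _bw(g):
            dot = (g * s).sum(axis=axis, keepdims=True)
            return (s * (g - dot),)

        out._backward = _bw
        return out

    def log_softmax(self, axis: int = -1):
        shifted = self.data - self.data.max(axis=axis, keepdims=True)
        lse = np.log(np.exp(shifted).sum(axis=axis, keepdims=True))
        out = Tensor(shifted - lse, _prev=(self,))
        soft = np.exp(shifted - lse)

        def _bw(g):
            return (g - soft * g.sum(axis=axis, keepdims=True),)

        out._backward = _bw
        return out

    # ------------------------------------------------------------------ shape
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = Tensor(self.data.reshape(shape), _prev=(self,))
        out._backward = lambda g: (g.reshape(self.shape),)
        return out

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        out = Tensor(self.data.transpose(axes), _prev=(self,))
        out._backward = lambda g: (g.transpose(inv),)
        return out

    def swapaxes(self, a: int, b: int):
        out = Tensor(np.swapaxes(self.data, a, b), _prev=(self,))
        out._backward = lambda g: (np.swapaxes(g, a, b),)
        return out

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], _prev=(self,))

        def _bw(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            return (full,)

        out._backward = _bw
        return out

    # --------------------------------------------------------------- backward
    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.size != 1:
                raise ValueError("backward() without a gradient requires a scalar output")
            grad = np.ones_like(self.data)

        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS: recurrent graphs can be deep
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._prev:
                stack.append((p, False))

        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=self.data.dtype)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            node.grad = g if node.grad is None else node.grad + g
            if node._backward is None:
                continue
            for parent, pg in zip(node._prev, node._backward(g)):
                if not parent.requires_grad:
                    continue
                if id(parent) in grads:
                    grads[id(parent)] = grads[id(parent)] + pg
                else:
                    grads[id(parent)] = np.asarray(pg)


def concatenate(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), _prev=tuple(tensors))
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def _bw(g):
        return tuple(np.split(g, splits, axis=axis))

    out._backward = _bw
    return out


def stack(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    out = Tensor(np.stack([t.data for t in tensors], axis=axis), _prev=tuple(tensors))

    def _bw(g):
        return tuple(np.moveaxis(g, axis, 0))

    out._backward = _bw
    return out
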