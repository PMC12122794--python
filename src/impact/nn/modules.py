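"""Layer primitives (Linear, LayerNorm, Dropout) on top of the autograd engine.

Weight matrices use Kaiming (He) normal initialization, std = sqrt(2 / fan_in),
optionally scaled by an extra factor (attention projections are scaled by
1/sqrt(n_heads)); biases start at exactly zero.
"""

from __future__ import annotations

from typing import Iterator

import numpy as np

from .tensor import Tensor

__all__ = ["Parameter", "Module", "Linear", "LayerNorm", "Dropout"]


class Parameter(Tensor):
    __slots__ = ("trainable",)

    def __init__(self, data):
        super().__init__(data, requires_grad=True)
        self.trainable = True


class Module:
    """Minimal module container: parameter discovery, train/eval mode, zero_grad."""

    def __init__(self):
        self.training = True

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Parameter]]:
        for name, attr in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(attr, Parameter):
                yield full, attr
            elif isinstance(attr, Module):
                yield from attr.named_parameters(f"{full}.")
            elif isinstance(attr, (list, tuple)):
                for i, item in enumerate(attr):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{full}.{i}.")
                    elif isinstance(item, Parameter):
                        yield f"{full}.{i}", item

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def astype(self, dtype) -> "Module":
        """Cast all parameters (e.g. to float32 for faster training)."""
        for p in self.parameters():
            p.data = p.data.astype(dtype)
        return self

    def train(self) -> "Module":
        self.training = True
        for m in self._child_modules():
            m.train()
        return self

    def eval(self) -> "Module":
        self.training = False
        for m in self._child_modules():
            m.eval()
        return self

    def _child_modules(self) -> list["Module"]:
        out = []
        for attr in vars(self).values():
            if isinstance(attr, Module):
                out.append(attr)
            elif isinstance(attr, (list, tuple)):
                out.extend(a for a in attr if isinstance(a, Module))
        return out

    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        if set(params) != set(state):
            missing = set(params) ^ set(state)
            raise KeyError(f"state dict mismatch: {sorted(missing)}")
        for name, value in state.items():
            params[name].data = np.array(value, dtype=np.float64)

    def n_parameters(self) -> int:
        return sum(p.size for p in self.parameters())


def kaiming_normal(rng: np.random.Generator, fan_in: int, fan_out: int,
                   scale: float = 1.0) -> np.ndarray:
    std = np.sqrt(2.0 / fan_in) * scale
    return rng.normal(0.0, std, size=(fan_in, fan_out))


class Linear(Module):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator,
                 bias: bool = True, init_scale: float = 1.0):
        super().__init__()
        self.in_dim = in_dim
        self.out_dim = out_dim
        self.weight = Parameter(kaiming_normal(rng, in_dim, out_dim, init_scale))
        self.bias = Parameter(np.zeros(out_dim)) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        if x.shape[-1] != self.in_dim:
            raise ValueError(f"Linear expected last dim {self.in_dim}, got {x.shape[-1]}")
        y = x @ self.weight
        return y + self.bias if self.bias is not None else y


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        super().__init__()
        self.dim = dim
        self.eps = eps
        self.gamma = Parameter(np.ones(dim))
        self.beta = Parameter(np.zeros(dim))

    def __call__(self, x: Tensor) -> Tensor:
        # fused op with an analytic vector-Jacobian product (hot path)
        mu = x.data.mean(axis=-1, keepdims=True)
        centered = x.data - mu
        var = (centered * centered).mean(axis=-1, keepdims=True)
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = centered * inv_std
        gamma, beta = self.gamma, self.beta
        out = Tensor(xhat * gamma.data + beta.data, _prev=(x, gamma, beta))

        def _bw(g):
            dxhat = g * gamma.data
            m1 = dxhat.mean(axis=-1, keepdims=True)
            m2 = (dxhat * xhat).mean(axis=-1, keepdims=True)
            dx = inv_std * (dxhat - m1 - xhat * m2)
            reduce_axes = tuple(range(g.ndim - 1))
            dgamma = (g * xhat).sum(axis=reduce_axes)
            dbeta = g.sum(axis=reduce_axes)
            return dx, dgamma, dbeta

        out._backward = _bw
        return out


class Dropout(Module):
    """Inverted dropout; active only in training mode, seeded by its own stream."""

    def __init__(self, p: float, rng: np.random.Generator):
        super().__init__()
        if not 0.0 <= p < 1.0:
            raise ValueError(f"dropout probability must be in [0, 1), got {p}")
        self.p = p
        self.rng = rng

    def __call__(self, x: Tensor) -> Tensor:
        if not self.training or self.p == 0.0:
            return x
        mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * Tensor(mask)
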