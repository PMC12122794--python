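"""AdamW with decoupled weight decay, global-norm gradient clipping, and the
one-cycle learning-rate policy (cosine warmup to a peak, cosine anneal to a
small floor)."""

from __future__ import annotations

import numpy as np

from .modules import Parameter

__all__ = ["AdamW", "OneCycleLR", "clip_grad_norm"]


def clip_grad_norm(params: list[Parameter], max_norm: float) -> float:
    """Scale all gradients so their joint L2 norm is at most ``max_norm``.

    Returns the pre-clipping norm.
    """
    total = 0.0
    for p in params:
        if p.grad is not None:
            total += float((p.grad**2).sum())
    norm = float(np.sqrt(total))
    if norm > max_norm and norm > 0:
        scale = max_norm / norm
        for p in params:
            if p.grad is not None:
                p.grad = p.grad * scale
    return norm


class AdamW:
    def __init__(self, params: list[Parameter], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 1e-4):
        self.params = list(params)
        self.lr = lr
        self.betas = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        b1, b2 = self.betas
        self.t += 1
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self._m[i] = b1 * self._m[i] + (1 - b1) * g
            self._v[i] = b2 * self._v[i] + (1 - b2) * g * g
            m_hat = self._m[i] / bc1
            v_hat = self._v[i] / bc2
            # decoupled decay: applied to the weights, not the gradient
            p.data = p.data - self.lr * (m_hat / (np.sqrt(v_hat) + self.eps)
                                         + self.weight_decay * p.data)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None


class OneCycleLR:
    """Cosine one-cycle schedule.

    lr rises from ``max_lr / div_factor`` to ``max_lr`` over the first
    ``pct_start`` fraction of steps, then anneals to
    ``max_lr / div_factor / final_div_factor``.
    """

    def __init__(self, optimizer: AdamW, max_lr: float, total_steps: int,
                 pct_start: float = 0.3, div_factor: float = 25.0,
                 final_div_factor: float = 1000.0):
        if not 0.0 < pct_start < 1.0:
            raise ValueError("pct_start must lie in (0, 1)")
        if total_steps < 2:
            raise ValueError("total_steps must be at least 2")
        self.optimizer = optimizer
        self.max_lr = max_lr
        self.total_steps = total_steps
        self.pct_start = pct_start
        self.initial_lr = max_lr / div_factor
        self.final_lr = self.initial_lr / final_div_factor
        self.peak_step = max(1, int(round(pct_start * (total_steps - 1))))
        self._step = 0
        optimizer.lr = self.lr_at(0)

    def lr_at(self, step: int) -> float:
        step = min(step, self.total_steps - 1)
        if step <= self.peak_step:
            frac = step / self.peak_step
            lo, hi = self.initial_lr, self.max_lr
        else:
            frac = (step - self.peak_step) / (self.total_steps - 1 - self.peak_step)
            lo, hi = self.max_lr, self.final_lr
        return lo + (hi - lo) * 0.5 * (1.0 - np.cos(np.pi * frac))

    def step(self) -> float:
        self._step += 1
        lr = self.lr_at(self._step)
        self.optimizer.lr = lr
        return lr
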