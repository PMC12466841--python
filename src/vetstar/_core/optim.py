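"""Optimisers and learning-rate schedules."""

from __future__ import annotations

import math

import numpy as np

__all__ = ["Adam", "EMA", "cosine_lr"]


class Adam:
    """Adam with optional per-call learning rate override."""

    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.zero_grad()

    def step(self, lr: float | None = None):
        lr = self.lr if lr is None else lr
        self.t += 1
        bc1 = 1 - self.b1**self.t
        bc2 = 1 - self.b2**self.t
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p.data -= lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)


class EMA:
    """Exponential moving average of model parameters.

    The decay ramps up as ``decay · (1 − exp(−t/tau))`` so the average tracks
    quickly at the start of training.  Buffers (batch-norm running statistics)
    are taken from the live model, which already maintains its own averages.
    """

    def __init__(self, model, decay: float = 0.999, tau: float = 100.0):
        self.model = model
        self.decay = decay
        self.tau = tau
        self.t = 0
        self.shadow = {k: p.data.copy() for k, p in model.named_parameters()}

    def update(self) -> None:
        self.t += 1
        d = self.decay * (1.0 - math.exp(-self.t / self.tau))
        for k, p in self.model.named_parameters():
            self.shadow[k] *= d
            self.shadow[k] += (1.0 - d) * p.data

    def state_dict(self) -> dict:
        state = self.model.state_dict()
        state.update({k: v.copy() for k, v in self.shadow.items()})
        return state


def cosine_lr(base_lr: float, epoch: int, max_epochs: int, min_frac: float = 0.05) -> float:
    """Cosine decay from ``base_lr`` to ``min_frac * base_lr`` over ``max_epochs``."""
    t = min(epoch / max(max_epochs - 1, 1), 1.0)
    return base_lr * (min_frac + (1 - min_frac) * 0.5 * (1 + math.cos(math.pi * t)))
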