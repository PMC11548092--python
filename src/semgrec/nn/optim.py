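"""Adadelta: per-parameter adaptive steps from running RMS of gradients and
updates (decay rho = 0.9, eps = 1e-6), with an overall step scale ``lr``.

With lr = 1.0 this is the canonical method; smaller values uniformly shrink
every update.
"""
from __future__ import annotations

import numpy as np

from .layers import Param

__all__ = ["Adadelta"]


class Adadelta:
    def __init__(self, params: list[Param], lr: float = 1.0, rho: float = 0.9,
                 eps: float = 1e-6):
        self.params = params
        self.lr = lr
        self.rho = rho
        self.eps = eps
        self._Eg = [np.zeros_like(p.value) for p in params]
        self._Ed = [np.zeros_like(p.value) for p in params]

    def step(self) -> None:
        for p, Eg, Ed in zip(self.params, self._Eg, self._Ed):
            g = p.grad
            Eg *= self.rho
            Eg += (1 - self.rho) * g * g
            dx = -np.sqrt((Ed + self.eps) / (Eg + self.eps)) * g
            Ed *= self.rho
            Ed += (1 - self.rho) * dx * dx
            p.value += self.lr * dx

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0
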