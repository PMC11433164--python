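"""Optimisation: Adam and reduce-on-plateau learning-rate scheduling."""

from __future__ import annotations

import numpy as np


class Adam:
    """Adam with the standard bias-corrected moment estimates."""

    def __init__(self, params, lr=1e-4, betas=(0.9, 0.999), eps=1e-8):
        self.params = list(params)
        self.lr = float(lr)
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None


class ReduceLROnPlateau:
    """Multiply the learning rate by ``factor`` after ``patience`` epochs
    without improvement of the monitored (validation) loss."""

    def __init__(self, optimizer: Adam, patience: int = 3, factor: float = 0.1,
                 min_lr: float = 0.0):
        self.optimizer = optimizer
        self.patience = int(patience)
        self.factor = float(factor)
        self.min_lr = float(min_lr)
        self.best = np.inf
        self.bad_epochs = 0

    def step(self, metric: float) -> bool:
        """Record one epoch's metric; returns True if the rate was reduced."""
        if metric < self.best:
            self.best = metric
            self.bad_epochs = 0
            return False
        self.bad_epochs += 1
        if self.bad_epochs >= self.patience:
            self.optimizer.lr = max(self.optimizer.lr * self.factor, self.min_lr)
            self.bad_epochs = 0
            return True
        return False
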