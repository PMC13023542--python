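"""Adam with global gradient-norm clipping, plateau LR decay, early stopping."""

from __future__ import annotations

import numpy as np

from apneaseg.nn.tensor import Tensor


class Adam:
    """Adam over an explicit parameter list; frozen layers are simply
    excluded from the list, so their values can never change."""

    def __init__(self, params: list[Tensor], lr: float = 1e-4,
                 beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8, clipnorm: float | None = 1.0):
        self.params = list(params)
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.clipnorm = clipnorm
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        grads = [p.grad if p.grad is not None else np.zeros_like(p.data)
                 for p in self.params]
        if self.clipnorm is not None:
            total = np.sqrt(sum(float((g ** 2).sum()) for g in grads))
            if total > self.clipnorm and total > 0:
                scale = self.clipnorm / total
                grads = [g * scale for g in grads]
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1 - b1 ** self.t
        bc2 = 1 - b2 ** self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m[...] = b1 * m + (1 - b1) * g
            v[...] = b2 * v + (1 - b2) * g * g
            p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()


class ReduceLROnPlateau:
    """Halve the learning rate when the monitored loss stops improving."""

    def __init__(self, optimizer: Adam, factor: float = 0.5,
                 patience: int = 2, min_lr: float = 1e-6):
        self.opt = optimizer
        self.factor = factor
        self.patience = patience
        self.min_lr = min_lr
        self.best = np.inf
        self.bad = 0

    def step(self, loss: float) -> None:
        if loss < self.best - 1e-12:
            self.best = loss
            self.bad = 0
            return
        self.bad += 1
        if self.bad > self.patience:
            self.opt.lr = max(self.opt.lr * self.factor, self.min_lr)
            self.bad = 0


class EarlyStopping:
    """Stop after ``patience`` epochs without improvement; tracks the best
    epoch so the caller can restore its weights (mode 'max' for F1-like
    metrics, 'min' for losses)."""

    def __init__(self, patience: int = 3, mode: str = "max"):
        self.patience = patience
        self.mode = mode
        self.best = -np.inf if mode == "max" else np.inf
        self.best_epoch = -1
        self.bad = 0

    def update(self, value: float, epoch: int) -> bool:
        """Record ``value``; return True when training should stop."""
        better = (value > self.best) if self.mode == "max" else (value < self.best)
        if better:
            self.best = value
            self.best_epoch = epoch
            self.bad = 0
            return False
        self.bad += 1
        return self.bad >= self.patience
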