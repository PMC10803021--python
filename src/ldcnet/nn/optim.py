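"""AdamW optimizer and a reduce-on-plateau learning-rate schedule."""

from __future__ import annotations

import numpy as np


class AdamW:
    """Adam with decoupled weight decay (Loshchilov & Hutter)."""

    def __init__(self, params, lr=1e-3, betas=(0.9, 0.999), eps=1e-8,
                 weight_decay=1e-2):
        self.params = list(params)
        self.lr = float(lr)
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        bc1 = 1.0 - self.beta1 ** self.t
        bc2 = 1.0 - self.beta2 ** self.t
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.beta1
            m += (1.0 - self.beta1) * g
            v *= self.beta2
            v += (1.0 - self.beta2) * g * g
            update = (m / bc1) / (np.sqrt(v / bc2) + self.eps)
            p.data -= self.lr * (update + self.weight_decay * p.data)


class ReduceLROnPlateau:
    """Scale the learning rate by ``factor`` when a metric stops improving.

    ``mode='max'`` treats larger metric values as better (e.g. validation
    mIoU); ``patience`` counts consecutive non-improving steps.
    """

    def __init__(self, optimizer, mode="max", factor=0.5, patience=5,
                 min_lr=1e-6, threshold=1e-4):
        if not 0.0 < factor < 1.0:
            raise ValueError("factor must be in (0, 1)")
        self.optimizer = optimizer
        self.mode = mode
        self.factor = factor
        self.patience = patience
        self.min_lr = min_lr
        self.threshold = threshold
        self.best = -np.inf if mode == "max" else np.inf
        self.num_bad = 0

    def _improved(self, metric):
        if self.mode == "max":
            return metric > self.best + self.threshold
        return metric < self.best - self.threshold

    def step(self, metric):
        if self._improved(metric):
            self.best = metric
            self.num_bad = 0
        else:
            self.num_bad += 1
            if self.num_bad > self.patience:
                self.optimizer.lr = max(self.optimizer.lr * self.factor,
                                        self.min_lr)
                self.num_bad = 0
        return self.optimizer.lr
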