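"""AdamW with a linear warm-up / linear decay schedule.

Parameters are a flat dict name -> array, updated in place. Weight decay is
decoupled (applied directly to the weights, not through the moments) and
skipped for one-dimensional parameters (biases, layer-norm gains,
embedding-free vectors), the usual transformer convention.
"""

from __future__ import annotations

import numpy as np


class LinearWarmupSchedule:
    """Linear ramp to ``base_lr`` over the first ``warmup_frac`` of steps, then linear decay to 0."""

    def __init__(self, base_lr: float, total_steps: int, warmup_frac: float = 0.1):
        self.base_lr = base_lr
        self.total_steps = max(int(total_steps), 1)
        self.warmup_steps = max(int(round(warmup_frac * self.total_steps)), 1)

    def lr(self, step: int) -> float:
        if step < self.warmup_steps:
            return self.base_lr * (step + 1) / self.warmup_steps
        remaining = self.total_steps - self.warmup_steps
        if remaining <= 0:
            return self.base_lr
        frac = (step - self.warmup_steps) / remaining
        return self.base_lr * max(0.0, 1.0 - frac)


class AdamW:
    def __init__(self, params: dict[str, np.ndarray], lr: float = 1e-4,
                 betas=(0.9, 0.999), eps: float = 1e-8, weight_decay: float = 0.01,
                 schedule: LinearWarmupSchedule | None = None):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.schedule = schedule
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, grads: dict[str, np.ndarray]) -> None:
        lr = self.schedule.lr(self.t) if self.schedule else self.lr
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for k, p in self.params.items():
            g = grads.get(k)
            if g is None:
                continue
            m = self.m[k]
            v = self.v[k]
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            update = (m / b1t) / (np.sqrt(v / b2t) + self.eps)
            if self.weight_decay and p.ndim > 1:
                update = update + self.weight_decay * p
            p -= lr * update
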