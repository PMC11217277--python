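"""Adam-family first-order optimizers with inverse-time learning-rate decay.

All four update rules used in the hyperparameter study are provided:
Adam, Nadam, AdamW (decoupled weight decay) and Lion (sign momentum).
The learning rate at update step t (0-based) is ``lr0 / (1 + decay * t)``,
the legacy inverse-time semantics of the "decay" argument.
"""

from __future__ import annotations

import numpy as np

__all__ = ["make_optimizer", "Adam", "Nadam", "AdamW", "Lion"]


class _Optimizer:
    def __init__(self, params: list, learning_rate: float = 1e-3,
                 decay: float = 5e-6):
        if learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        self.params = params
        self.lr0 = learning_rate
        self.decay = decay
        self.t = 0

    @property
    def lr(self) -> float:
        return self.lr0 / (1.0 + self.decay * self.t)

    def step(self, grads: list) -> None:
        lr = self.lr
        self.t += 1
        self._apply(grads, lr)

    def _apply(self, grads: list, lr: float) -> None:  # pragma: no cover
        raise NotImplementedError


class Adam(_Optimizer):
    def __init__(self, params, learning_rate=1e-3, decay=5e-6,
                 beta_1=0.9, beta_2=0.999, epsilon=1e-7):
        super().__init__(params, learning_rate, decay)
        self.b1, self.b2, self.eps = beta_1, beta_2, epsilon
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]

    def _apply(self, grads, lr):
        t = self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m[...] = self.b1 * m + (1 - self.b1) * g
            v[...] = self.b2 * v + (1 - self.b2) * g * g
            mhat = m / (1 - self.b1**t)
            vhat = v / (1 - self.b2**t)
            p -= lr * mhat / (np.sqrt(vhat) + self.eps)


class Nadam(Adam):
    """Adam with Nesterov momentum applied to the first-moment estimate."""

    def _apply(self, grads, lr):
        t = self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m[...] = self.b1 * m + (1 - self.b1) * g
            v[...] = self.b2 * v + (1 - self.b2) * g * g
            mhat = (self.b1 * m + (1 - self.b1) * g) / (1 - self.b1 ** (t + 1))
            vhat = v / (1 - self.b2**t)
            p -= lr * mhat / (np.sqrt(vhat) + self.eps)


class AdamW(Adam):
    """Adam with decoupled weight decay (applied multiplicatively per step)."""

    def __init__(self, params, learning_rate=1e-3, decay=5e-6,
                 beta_1=0.9, beta_2=0.999, epsilon=1e-7, weight_decay=4e-3):
        super().__init__(params, learning_rate, decay, beta_1, beta_2, epsilon)
        self.wd = weight_decay

    def _apply(self, grads, lr):
        for p in self.params:
            p -= lr * self.wd * p
        super()._apply(grads, lr)


class Lion(_Optimizer):
    """Sign-momentum optimizer (evoLved sign momentum)."""

    def __init__(self, params, learning_rate=1e-3, decay=5e-6,
                 beta_1=0.9, beta_2=0.99):
        super().__init__(params, learning_rate, decay)
        self.b1, self.b2 = beta_1, beta_2
        self.m = [np.zeros_like(p) for p in params]

    def _apply(self, grads, lr):
        for p, g, m in zip(self.params, grads, self.m):
            p -= lr * np.sign(self.b1 * m + (1 - self.b1) * g)
            m[...] = self.b2 * m + (1 - self.b2) * g


_REGISTRY = {"adam": Adam, "nadam": Nadam, "adamw": AdamW, "lion": Lion}


def make_optimizer(name: str, params: list, **kw) -> _Optimizer:
    try:
        cls = _REGISTRY[name.lower()]
    except KeyError:
        raise ValueError(
            f"unknown optimizer {name!r}; choose from {sorted(_REGISTRY)}"
        ) from None
    return cls(params, **kw)
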