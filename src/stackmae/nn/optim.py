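"""Optimizers and the warmup + cosine learning-rate schedule."""

from __future__ import annotations

import math

import numpy as np

from .tensor import Tensor


def warmup_cosine_lr(it: int, base_lr: float, warmup_iters: int, total_iters: int) -> float:
    """Linear warmup to ``base_lr`` then cosine decay to 0 at ``total_iters``."""
    if warmup_iters > 0 and it < warmup_iters:
        return base_lr * (it + 1) / warmup_iters
    span = max(1, total_iters - warmup_iters)
    t = min(1.0, (it - warmup_iters) / span)
    return 0.5 * base_lr * (1.0 + math.cos(math.pi * t))


class Optimizer:
    def __init__(self, params: list[Tensor], lr: float):
        self.params = list(params)
        self.lr = lr

    def zero_grad(self):
        for p in self.params:
            p.zero_grad()

    def state_dict(self) -> dict:
        raise NotImplementedError

    def load_state_dict(self, state: dict):
        raise NotImplementedError


class AdamW(Optimizer):
    """Adam with decoupled weight decay."""

    def __init__(
        self,
        params: list[Tensor],
        lr: float = 1e-4,
        betas: tuple[float, float] = (0.9, 0.95),
        weight_decay: float = 0.005,
        eps: float = 1e-8,
    ):
        super().__init__(params, lr)
        self.betas = betas
        self.weight_decay = weight_decay
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        self.t += 1
        b1, b2 = self.betas
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / bc1
            vhat = self.v[i] / bc2
            p.data -= self.lr * (mhat / (np.sqrt(vhat) + self.eps) + self.weight_decay * p.data)

    def state_dict(self) -> dict:
        return {
            "t": self.t,
            "m": [m.copy() for m in self.m],
            "v": [v.copy() for v in self.v],
        }

    def load_state_dict(self, state: dict):
        self.t = int(state["t"])
        self.m = [np.asarray(m, dtype=np.float32).copy() for m in state["m"]]
        self.v = [np.asarray(v, dtype=np.float32).copy() for v in state["v"]]


class SGD(Optimizer):
    """SGD with classical momentum and coupled weight decay."""

    def __init__(
        self,
        params: list[Tensor],
        lr: float = 4e-3,
        momentum: float = 0.9,
        weight_decay: float = 1e-4,
    ):
        super().__init__(params, lr)
        self.momentum = momentum
        self.weight_decay = weight_decay
        self.buf = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad + self.weight_decay * p.data
            self.buf[i] = self.momentum * self.buf[i] + g
            p.data -= self.lr * self.buf[i]

    def state_dict(self) -> dict:
        return {"buf": [b.copy() for b in self.buf]}

    def load_state_dict(self, state: dict):
        self.buf = [np.asarray(b, dtype=np.float32).copy() for b in state["buf"]]
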