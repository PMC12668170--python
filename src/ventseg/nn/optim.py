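"""AdamW optimizer (decoupled weight decay)."""

from __future__ import annotations

import numpy as np

from .tensor import Tensor

__all__ = ["AdamW"]


class AdamW:
    """Adam with decoupled weight decay.

    Decay is applied only to parameters listed in ``params``; pass
    auxiliary parameters (biases, norm scales, learned loss log-variances)
    via ``no_decay_params`` so they are updated without shrinkage, the
    standard convention.
    """

    def __init__(
        self,
        params: list[Tensor],
        lr: float = 5e-4,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        weight_decay: float = 1e-2,
        no_decay_params: list[Tensor] | None = None,
    ):
        self.groups = [(list(params), weight_decay), (list(no_decay_params or []), 0.0)]
        self.lr = lr
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.t = 0
        self.state = {
            id(p): (np.zeros_like(p.data), np.zeros_like(p.data))
            for group, _ in self.groups
            for p in group
        }

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for group, wd in self.groups:
            for p in group:
                if p.grad is None:
                    continue
                g = p.grad.astype(p.data.dtype)
                m, v = self.state[id(p)]
                m = b1 * m + (1 - b1) * g
                v = b2 * v + (1 - b2) * g * g
                self.state[id(p)] = (m, v)
                update = (m / bc1) / (np.sqrt(v / bc2) + self.eps)
                p.data = p.data - self.lr * (update + wd * p.data)

    def zero_grad(self) -> None:
        for group, _ in self.groups:
            for p in group:
                p.zero_grad()
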