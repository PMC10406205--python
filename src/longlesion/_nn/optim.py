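"""Adam optimizer (Kingma & Ba) over the engine's named parameters."""

from __future__ import annotations

from typing import Dict, List, Tuple

import numpy as np

from .autograd import Tensor

__all__ = ["Adam"]


class Adam:
    def __init__(
        self,
        named_params: List[Tuple[str, Tensor]] | Dict[str, Tensor],
        lr: float = 1e-4,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ) -> None:
        items = named_params.items() if isinstance(named_params, dict) else named_params
        # only trainable parameters are tracked; frozen ones are never touched
        self.params = [(n, t) for n, t in items if t.requires_grad]
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = {n: np.zeros_like(t.data) for n, t in self.params}
        self.v = {n: np.zeros_like(t.data) for n, t in self.params}

    def zero_grad(self) -> None:
        for _, t in self.params:
            t.grad = None

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t
        for n, t in self.params:
            if t.grad is None:
                continue
            g = t.grad.astype(np.float64)
            self.m[n] = b1 * self.m[n] + (1 - b1) * g
            self.v[n] = b2 * self.v[n] + (1 - b2) * g * g
            mhat = self.m[n] / bc1
            vhat = self.v[n] / bc2
            t.data = (t.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(
                t.data.dtype
            )
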