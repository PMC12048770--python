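"""Adam optimizer with parameter groups (per-group learning rates)."""

from __future__ import annotations

import numpy as np

from .modules import Parameter


class Adam:
    """Adam with decoupled group learning rates and L2 weight decay.

    ``groups`` is a list of dicts with keys ``params`` (list of Parameter),
    ``lr`` and optionally ``name``.  ``beta1`` doubles as the momentum knob
    the training schedule ramps during warm-up.
    """

    def __init__(
        self,
        groups: list[dict],
        beta1: float = 0.937,
        beta2: float = 0.999,
        eps: float = 1e-8,
        weight_decay: float = 0.0005,
    ):
        self.groups = []
        for g in groups:
            params = list(g["params"])
            self.groups.append(
                {
                    "params": params,
                    "lr": float(g["lr"]),
                    "name": g.get("name", ""),
                    "m": [np.zeros_like(p.data) for p in params],
                    "v": [np.zeros_like(p.data) for p in params],
                }
            )
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0

    def zero_grad(self) -> None:
        for g in self.groups:
            for p in g["params"]:
                p.grad = None

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t
        for g in self.groups:
            lr = g["lr"]
            for p, m, v in zip(g["params"], g["m"], g["v"]):
                if p.grad is None:
                    continue
                grad = p.grad
                if self.weight_decay:
                    grad = grad + self.weight_decay * p.data
                m *= b1
                m += (1.0 - b1) * grad
                v *= b2
                v += (1.0 - b2) * grad * grad
                p.data -= lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
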