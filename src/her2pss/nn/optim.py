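"""AdamW optimizer (decoupled weight decay)."""

from __future__ import annotations

import numpy as np

__all__ = ["AdamW"]


class AdamW:
    """Adam with decoupled weight decay.

    Update per parameter p with gradient g:
      m <- b1 m + (1-b1) g;  v <- b2 v + (1-b2) g^2
      p <- p - lr * ( m_hat / (sqrt(v_hat) + eps) + weight_decay * p )
    Bias vectors (1-D parameters) are not decayed.
    """

    def __init__(
        self,
        params: list[np.ndarray],
        lr: float = 1e-3,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        weight_decay: float = 1e-4,
    ) -> None:
        self.params = params
        self.lr = float(lr)
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = float(weight_decay)
        self.t = 0
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v, strict=True):
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * np.square(g)
            update = (m / b1t) / (np.sqrt(v / b2t) + self.eps)
            if p.ndim > 1 and self.weight_decay:
                update = update + self.weight_decay * p
            p -= np.float32(self.lr) * update
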