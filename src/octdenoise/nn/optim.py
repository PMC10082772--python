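"""Adam optimizer over the layer parameter dicts."""

from __future__ import annotations

import numpy as np

from .layers import Layer


class Adam:
    """Adam with bias correction; ``lr`` is mutable between steps."""

    def __init__(self, layers: list[Layer], lr: float,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8) -> None:
        self.lr = float(lr)
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self._slots = []
        for lyr in layers:
            for name, p in lyr.params.items():
                self._slots.append((lyr, name, np.zeros_like(p), np.zeros_like(p)))

    def zero_grad(self) -> None:
        for lyr, name, _, _ in self._slots:
            lyr.grads[name][...] = 0.0

    def step(self) -> None:
        self.t += 1
        c1 = 1.0 - self.b1 ** self.t
        c2 = 1.0 - self.b2 ** self.t
        for lyr, name, m, v in self._slots:
            g = lyr.grads[name]
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            lyr.params[name] -= self.lr * (m / c1) / (np.sqrt(v / c2) + self.eps)
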