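"""RMSprop optimizer over the network's flat parameter list."""

from __future__ import annotations

from typing import Dict, List, Tuple

import numpy as np


class RMSprop:
    """Root-mean-square propagation with the conventional defaults
    (learning rate 1e-3, decay rho 0.9, epsilon 1e-7)."""

    def __init__(self, learning_rate: float = 1e-3, rho: float = 0.9,
                 eps: float = 1e-7) -> None:
        self.learning_rate = learning_rate
        self.rho = rho
        self.eps = eps
        self._cache: Dict[int, np.ndarray] = {}

    def step(self, params_and_grads: List[Tuple[np.ndarray, np.ndarray]]) -> None:
        """In-place update; ``params_and_grads`` pairs must arrive in a
        stable order so the per-slot caches line up across steps."""
        for slot, (p, g) in enumerate(params_and_grads):
            cache = self._cache.get(slot)
            if cache is None:
                cache = np.zeros_like(p)
                self._cache[slot] = cache
            cache *= self.rho
            cache += (1.0 - self.rho) * g * g
            p -= self.learning_rate * g / (np.sqrt(cache) + self.eps)
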