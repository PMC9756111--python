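"""Small internal numerics helpers shared across modules."""

from __future__ import annotations

import numpy as np


def numeric_hessian(fn, x: np.ndarray, eps: float = 1e-4) -> np.ndarray:
    """Central-difference Hessian of a scalar function."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    h = np.empty((n, n))
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n); ei[i] = eps
            ej = np.zeros(n); ej[j] = eps
            h[i, j] = h[j, i] = (
                fn(x + ei + ej) - fn(x + ei - ej) - fn(x - ei + ej) + fn(x - ei - ej)
            ) / (4 * eps * eps)
    return h


# Fixed stream ids so adding a generator never perturbs existing ones.
_STREAMS = {
    "lifetimes": 11,
    "diffusion": 12,
    "bleach": 13,
    "labels": 14,
    "kymogram": 15,
    "wlc": 16,
}


def child_rng(seed: int, stream: str) -> np.random.Generator:
    """Deterministic per-generator child stream of one root seed."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), _STREAMS[stream]]))
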