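"""Central finite differences for derivatives the model does not supply."""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np


def central_difference(f: Callable[[float], float], x: float, h: float = 1e-5) -> float:
    """Second-order central difference f'(x) with a relative step."""
    step = h * max(1.0, abs(x))
    return (f(x + step) - f(x - step)) / (2.0 * step)


def gradient(f: Callable[[np.ndarray], float], x: Sequence[float], h: float = 1e-6) -> np.ndarray:
    """Central-difference gradient of a scalar function of a vector."""
    x = np.asarray(x, dtype=float)
    g = np.empty_like(x)
    for k in range(x.size):
        step = h * max(1.0, abs(x[k]))
        xp, xm = x.copy(), x.copy()
        xp[k] += step
        xm[k] -= step
        g[k] = (f(xp) - f(xm)) / (2.0 * step)
    return g


def jacobian(f: Callable[[np.ndarray], np.ndarray], x: Sequence[float], h: float = 1e-6) -> np.ndarray:
    """Central-difference Jacobian of a vector function of a vector."""
    x = np.asarray(x, dtype=float)
    f0 = np.asarray(f(x), dtype=float)
    J = np.empty((f0.size, x.size))
    for k in range(x.size):
        step = h * max(1.0, abs(x[k]))
        xp, xm = x.copy(), x.copy()
        xp[k] += step
        xm[k] -= step
        J[:, k] = (np.asarray(f(xp)) - np.asarray(f(xm))) / (2.0 * step)
    return J
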