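"""Small shared numerical-differentiation helpers."""

from __future__ import annotations

import numpy as np


def fd_jacobian(f, y: np.ndarray, eps: float = 1e-7) -> np.ndarray:
    """Central-difference Jacobian of f at y (f maps R^n -> R^n)."""
    y = np.asarray(y, dtype=float)
    n = y.size
    J = np.empty((n, n))
    for j in range(n):
        step = eps * max(1.0, abs(y[j]))
        yp = y.copy()
        ym = y.copy()
        yp[j] += step
        ym[j] -= step
        J[:, j] = (np.asarray(f(yp)) - np.asarray(f(ym))) / (2.0 * step)
    return J
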