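"""Shared statistical utilities.

Small primitives used across modules: Benjamini-Hochberg step-up adjustment
and the inverse trigamma function needed for empirical-Bayes variance
moderation.
"""

from __future__ import annotations

import numpy as np
from scipy import special


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    Sorts p ascending, computes ``p_(i) * n / i``, takes the running minimum
    from the largest rank down, clips at 1, and returns values in the input
    order. Ties are handled stably and the result is invariant to input
    order.

    Parameters
    ----------
    p : array-like of float in [0, 1]

    Returns
    -------
    numpy.ndarray of adjusted p-values, same length and order as the input.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("p must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any(np.isnan(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.clip(adj, 0.0, 1.0)
    out = np.empty(n, dtype=float)
    out[order] = adj
    return out


def trigamma_inverse(y: float, tol: float = 1e-8, max_iter: int = 100) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration.

    Used by the method-of-moments estimate of the prior degrees of freedom
    in variance moderation. Monotone decreasing, so Newton from the
    standard starting point ``0.5 + 1/y`` converges quickly.
    """
    if y <= 0:
        raise ValueError("trigamma_inverse requires y > 0")
    # asymptotic shortcuts for extreme arguments
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x = x + dif
        if abs(dif) < tol * max(x, 1.0):
            break
    return float(x)
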