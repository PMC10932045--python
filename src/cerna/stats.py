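"""Shared correlation primitives.

Every stage of the screening cascade (module-trait tables, pair screening,
replication, infiltration correlation) uses the same Pearson r, the same
two-sided Student-t p-value and the same Fisher-z confidence interval, so
they live in exactly one place.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = ["CorrelationResult", "ZeroVarianceError", "pearson", "corr_pvalue"]


class ZeroVarianceError(ValueError):
    """Raised when a correlation is requested for a constant vector.

    Correlation of a constant vector is undefined; callers that can tolerate
    missing values catch this and record the reason instead of a silent 0.
    """


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    n: int
    t: float
    p: float
    z_interval: tuple[float, float]


def corr_pvalue(r: float, n: int) -> float:
    """Two-sided p-value of the Student correlation test.

    t = r * sqrt(n - 2) / sqrt(1 - r^2) referred to a t distribution with
    n - 2 degrees of freedom.  |r| = 1 gives p = 0.
    """
    if n < 3:
        raise ValueError("correlation test needs n >= 3")
    if abs(r) >= 1.0:
        return 0.0
    t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
    return float(2.0 * sps.t.sf(abs(t), df=n - 2))


def pearson(x, y, *, ci_level: float = 0.95) -> CorrelationResult:
    """Product-moment correlation with Student test and Fisher-z interval.

    Inputs must be complete (no NaN) and of equal length >= 3; a constant
    vector raises :class:`ZeroVarianceError` naming the offender.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    n = x.size
    if n < 3:
        raise ValueError("pearson requires at least 3 observations")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("pearson requires finite, complete inputs")
    xc = x - x.mean()
    yc = y - y.mean()
    sx = np.sqrt(np.sum(xc * xc))
    sy = np.sqrt(np.sum(yc * yc))
    if sx == 0.0:
        raise ZeroVarianceError("x has zero variance; correlation undefined")
    if sy == 0.0:
        raise ZeroVarianceError("y has zero variance; correlation undefined")
    r = float(np.sum(xc * yc) / (sx * sy))
    r = max(-1.0, min(1.0, r))
    p = corr_pvalue(r, n)
    if abs(r) >= 1.0:
        t = np.inf if r > 0 else -np.inf
        lo, hi = r, r
    else:
        t = float(r * np.sqrt(n - 2) / np.sqrt(1.0 - r * r))
        if n > 3:
            z = np.arctanh(r)
            se = 1.0 / np.sqrt(n - 3)
            q = sps.norm.ppf(0.5 + ci_level / 2.0)
            lo, hi = float(np.tanh(z - q * se)), float(np.tanh(z + q * se))
        else:
            lo, hi = -1.0, 1.0
    return CorrelationResult(r=r, n=n, t=t, p=p, z_interval=(lo, hi))
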