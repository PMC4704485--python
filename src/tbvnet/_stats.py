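"""Shared statistical primitives used across the pipeline.

Correlation p-values use the Student asymptotic test
``t = r * sqrt(n - 2) / sqrt(1 - r**2)`` with ``n - 2`` degrees of freedom,
two-sided.  Group differences in correlation strength use Fisher's z
transform.  Permutation p-values follow the count/(n_perm + 1) convention.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

__all__ = [
    "pearson_r",
    "correlation_pvalue",
    "corr_test",
    "fisher_z",
    "zdiff_population",
    "permutation_pvalue",
]


def pearson_r(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation of two 1-d arrays; raises on constant input."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d arrays of equal length")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("correlation undefined for constant input")
    return float(np.corrcoef(x, y)[0, 1])


def correlation_pvalue(r: float, n: int) -> float:
    """Two-sided p-value for a Pearson correlation at sample size ``n``.

    Student asymptotic test: t = r sqrt(n-2) / sqrt(1-r^2), df = n-2.
    """
    if n < 3:
        raise ValueError("need at least 3 observations")
    r = float(np.clip(r, -1.0, 1.0))
    if abs(r) >= 1.0:
        return 0.0
    t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


def corr_test(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """(r, two-sided p) for a pair of vectors."""
    r = pearson_r(x, y)
    return r, correlation_pvalue(r, len(x))


def fisher_z(r: float | np.ndarray) -> float | np.ndarray:
    """Fisher z transform, clipped away from +-1 for numerical safety."""
    return np.arctanh(np.clip(r, -0.999999999, 0.999999999))


def zdiff_population(r1: float, r2: float, n1: int, n2: int) -> float:
    """z statistic for the difference of two independent correlations.

    ``(atanh(r1) - atanh(r2)) / sqrt(1/(n1-3) + 1/(n2-3))``.  Used as a
    population-level effect size when every member of the population is
    measured (e.g. all genes of a module), in which case no p-value is
    attached.
    """
    if n1 <= 3 or n2 <= 3:
        raise ValueError("group sizes must exceed 3")
    return float((fisher_z(r1) - fisher_z(r2)) / np.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3)))


def permutation_pvalue(count: int, n_perm: int) -> float:
    """Permutation p-value ``count / (n_perm + 1)``.

    A value of exactly 0 means "< 1/(n_perm+1)"; report layers annotate it
    rather than altering the number.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    return count / (n_perm + 1)
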