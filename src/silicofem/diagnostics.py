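"""Convergence diagnostics and cohort-equivalence testing.

Convergence of the realization ensemble is judged on the cumulative
mean fracture count: for each prefix length k, bootstrap resampling of
the first k and first k-1 counts estimates the relative change in the
mean brought by the k-th realization; the ensemble has converged at the
first k where that relative difference drops below a threshold
(1% by default).  Cohort equivalence against a clinical reference uses
the pooled two-sample t-test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple
import warnings

import numpy as np
from scipy import stats

__all__ = ["ConvergenceTrace", "convergence_check", "two_sample_ttest"]


@dataclass
class ConvergenceTrace:
    """Cumulative-mean trace with bootstrap and plain relative differences."""

    cumulative_means: np.ndarray  # length R
    bootstrap_rel_diffs: np.ndarray  # length R-1, entry j for prefix k = j+2
    plain_rel_diffs: np.ndarray  # same layout, |m_k - m_{k-1}| / m_{k-1}
    converged_at: Optional[int]  # first k with bootstrap rel diff <= threshold
    threshold: float


def convergence_check(
    counts,
    threshold: float = 0.01,
    rng: Optional[np.random.Generator] = None,
    n_boot: int = 10_000,
) -> ConvergenceTrace:
    """Bootstrap convergence diagnostic of the mean over realizations.

    For every k >= 2, ``n_boot`` bootstrap resamples (with replacement)
    of the first k counts and, paired, of the first k-1 counts are
    drawn; the relative difference is the mean over resample pairs of
    ``|M_k* - M_{k-1}*| / M_{k-1}*`` (pairs with a zero denominator are
    skipped).  An all-zero count sequence has zero relative difference
    by definition and converges immediately.
    """
    x = np.asarray(counts, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("need a 1-D array of at least 2 realization counts")
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    if rng is None:
        rng = np.random.default_rng()
    R = x.size

    cum_means = np.cumsum(x) / np.arange(1, R + 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        plain = np.abs(np.diff(cum_means)) / np.abs(cum_means[:-1])
    plain = np.where(np.isfinite(plain), plain, 0.0)

    boot = np.zeros(R - 1)
    if np.any(x != 0):
        for j, k in enumerate(range(2, R + 1)):
            idx_k = rng.integers(0, k, size=(n_boot, k))
            idx_km1 = rng.integers(0, k - 1, size=(n_boot, k - 1))
            m_k = x[idx_k].mean(axis=1)
            m_km1 = x[idx_km1].mean(axis=1)
            ok = m_km1 != 0
            boot[j] = np.mean(np.abs(m_k[ok] - m_km1[ok]) / m_km1[ok]) if ok.any() else 0.0

    below = np.flatnonzero(boot <= threshold)
    converged_at = int(below[0] + 2) if below.size else None
    return ConvergenceTrace(
        cumulative_means=cum_means,
        bootstrap_rel_diffs=boot,
        plain_rel_diffs=plain,
        converged_at=converged_at,
        threshold=threshold,
    )


def two_sample_ttest(a, b) -> Tuple[float, float]:
    """Pooled (equal-variance) two-sample t-test, two-sided.

    Matches the classic ttest2 contract: t with n_a + n_b - 2 degrees
    of freedom.  Degenerate zero-variance inputs: equal means give
    (0, 1); unequal means give (signed inf, 0) with a warning.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least 2 observations")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        warnings.warn("zero pooled variance with unequal means: degenerate t-test", RuntimeWarning)
        return float(np.sign(a.mean() - b.mean()) * np.inf), 0.0
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return float(t), float(p)
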