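"""Homogeneous Poisson fall process.

Falls in the community-dwelling elderly population are modelled as
discrete events with a constant mean rate lambda (falls per
person-year): equal event probability in every sub-interval, multiple
events per interval allowed, independence between intervals.  The rate
is homogeneous across patients and years (no frailty heterogeneity, no
fear-of-falling feedback); the literature-based default is
lambda = 0.65 falls/year.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

DEFAULT_FALL_RATE = 0.65  # falls per person-year

__all__ = ["FallSchedule", "poisson_pmf", "sample_fall_counts", "DEFAULT_FALL_RATE"]


@dataclass
class FallSchedule:
    """Per-patient fall counts over the follow-up years."""

    patient_id: str
    counts_per_year: np.ndarray  # integer array, length = follow-up years

    def __post_init__(self):
        self.counts_per_year = np.asarray(self.counts_per_year, dtype=int)
        if np.any(self.counts_per_year < 0):
            raise ValueError("fall counts must be non-negative")


def poisson_pmf(lam: float, n) -> float:
    """P(N = n) for N ~ Poisson(lam): lam^n e^-lam / n!."""
    n_arr = np.asarray(n)
    if lam < 0:
        raise ValueError("lam must be non-negative")
    if np.any(n_arr < 0) or not np.issubdtype(n_arr.dtype, np.integer):
        raise ValueError("n must be a non-negative integer")
    out = stats.poisson.pmf(n_arr, lam)
    return float(out) if np.ndim(n) == 0 else out


def sample_fall_counts(
    lam: float,
    n_patients: int,
    years: int,
    rng: np.random.Generator,
    patient_ids=None,
) -> list:
    """Draw i.i.d. Poisson(lam) fall counts for every patient-year."""
    if lam < 0:
        raise ValueError("lam must be non-negative")
    counts = rng.poisson(lam, size=(n_patients, years))
    if patient_ids is None:
        patient_ids = [f"P{i + 1:06d}" for i in range(n_patients)]
    return [FallSchedule(pid, row) for pid, row in zip(patient_ids, counts)]
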