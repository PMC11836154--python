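"""Markov-chain follow-up engine.

Each virtual patient is a two-state chain (active -> fractured, with
fractured absorbing) advanced in 1-year steps.  Per active patient-year
a Poisson(lambda) fall count is drawn; each fall gets a direction on
the 61x31 grid and an attenuated impact force, the direction-specific
failure load is looked up, and the patient fractures when the force
strictly exceeds the failure load.  A fractured patient's remaining
falls and years are discarded (hip fracture is the clinical endpoint).
One realization replays the whole cohort; incidence is summarised over
independent realizations spawned from a single master seed, with
per-realization, per-patient random sub-streams so edits to one
patient never perturb another's draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np

from .atlas import CohortTarget
from .diagnostics import ConvergenceTrace, convergence_check
from .impact import (
    ImpactParams,
    attenuate_force,
    impact_velocity,
    peak_impact_force,
    sample_fall_direction,
)
from .strength import lookup_failure_load

__all__ = ["TrialConfig", "TrialResult", "FractureRecord", "simulate_realization", "run_trial"]


@dataclass(frozen=True)
class TrialConfig:
    """Follow-up configuration; the time step is fixed at 1 year."""

    lam: float = 0.65  # falls per person-year
    years: int = 3
    n_realizations: int = 10
    convergence_threshold: float = 0.01
    master_seed: int = 0
    cohort: Optional[CohortTarget] = None
    timestep: int = 1

    def __post_init__(self):
        if self.lam < 0:
            raise ValueError("lam must be >= 0")
        if self.years < 1:
            raise ValueError("years must be >= 1")
        if self.n_realizations < 1:
            raise ValueError("n_realizations must be >= 1")
        if not 0 < self.convergence_threshold < 1:
            raise ValueError("convergence_threshold must be in (0, 1)")
        if self.timestep != 1:
            raise ValueError("the follow-up time step is fixed at 1 year")


@dataclass(frozen=True)
class FractureRecord:
    patient_id: str
    realization: int
    year: int  # 1-based
    alpha: int
    beta: int
    force: float  # N
    failure_load: float  # N


@dataclass
class TrialResult:
    """Ensemble summary of the fracture-incidence simulation."""

    fractures_per_realization: np.ndarray
    n_strength_evaluations_per_realization: np.ndarray
    per_year_counts: np.ndarray  # (n_realizations, years)
    records: List[FractureRecord]
    n_patients: int
    config: TrialConfig
    convergence: Optional[ConvergenceTrace] = None

    def __post_init__(self):
        self.fractures_per_realization = np.asarray(self.fractures_per_realization, dtype=int)
        self.n_strength_evaluations_per_realization = np.asarray(
            self.n_strength_evaluations_per_realization, dtype=int
        )
        self.per_year_counts = np.asarray(self.per_year_counts, dtype=int)
        if self.fractures_per_realization.size == 0:
            raise ValueError("a trial result needs at least one realization")
        if np.any(self.fractures_per_realization > self.n_patients):
            raise ValueError("fracture count cannot exceed cohort size")
        if not np.array_equal(self.per_year_counts.sum(axis=1), self.fractures_per_realization):
            raise ValueError("per-year counts must sum to realization totals")

    @property
    def mean(self) -> float:
        return float(self.fractures_per_realization.mean())

    @property
    def sd(self) -> float:
        x = self.fractures_per_realization
        return float(x.std(ddof=1)) if x.size > 1 else 0.0

    @property
    def min(self) -> int:
        return int(self.fractures_per_realization.min())

    @property
    def max(self) -> int:
        return int(self.fractures_per_realization.max())

    @property
    def incidence(self) -> float:
        """Mean 3-year fracture incidence as a fraction of the cohort."""
        return self.mean / self.n_patients


def simulate_realization(
    cohort: list,
    config: TrialConfig,
    seed: np.random.SeedSequence,
    impact: ImpactParams = ImpactParams(),
    realization_index: int = 0,
):
    """Run one realization of the chain over a fully active cohort.

    Returns ``(records, n_evaluations, per_year_counts)`` where
    ``n_evaluations`` counts strength lookups (one per processed fall,
    the stand-in for one FE simulation).
    """
    if not isinstance(seed, np.random.SeedSequence):
        seed = np.random.SeedSequence(seed)
    child_seeds = seed.spawn(len(cohort))
    records: List[FractureRecord] = []
    n_evaluations = 0
    per_year = np.zeros(config.years, dtype=int)

    for patient, ss in zip(cohort, child_seeds):
        rng = np.random.Generator(np.random.PCG64(ss))
        surface = patient.strength
        if surface is None:
            raise ValueError(f"patient {patient.id} has no strength surface attached")
        fractured = False
        for year in range(1, config.years + 1):
            n_falls = rng.poisson(config.lam)
            for _ in range(n_falls):
                alpha, beta = sample_fall_direction(rng)
                v = impact_velocity(patient.height, impact, rng)
                f_peak = peak_impact_force(patient.weight, v, impact)
                force = attenuate_force(f_peak, patient.soft_tissue_thickness, impact)
                failure_load = lookup_failure_load(surface, alpha, beta)
                n_evaluations += 1
                if force > failure_load:  # strictly "exceeded"
                    records.append(
                        FractureRecord(
                            patient_id=patient.id,
                            realization=realization_index,
                            year=year,
                            alpha=alpha,
                            beta=beta,
                            force=force,
                            failure_load=failure_load,
                        )
                    )
                    per_year[year - 1] += 1
                    fractured = True
                    break  # remaining falls this year discarded
            if fractured:
                break  # absorbing state: excluded from later years
    return records, n_evaluations, per_year


def run_trial(
    cohort: list,
    config: TrialConfig,
    impact: ImpactParams = ImpactParams(),
    n_boot: int = 10_000,
    compute_convergence: bool = True,
) -> TrialResult:
    """Run ``config.n_realizations`` independent realizations and aggregate.

    Every realization restarts the same cohort fully active.  All
    randomness derives from ``config.master_seed``; identical seeds
    reproduce identical results bit for bit.  The bootstrap convergence
    trace costs O(n_boot * n_realizations^2); disable it with
    ``compute_convergence=False`` for very large ensembles.
    """
    root = np.random.SeedSequence(config.master_seed)
    realization_seeds = root.spawn(config.n_realizations + 1)
    conv_seed = realization_seeds[-1]

    fractures = np.zeros(config.n_realizations, dtype=int)
    evals = np.zeros(config.n_realizations, dtype=int)
    per_year = np.zeros((config.n_realizations, config.years), dtype=int)
    records: List[FractureRecord] = []
    for r in range(config.n_realizations):
        recs, n_eval, py = simulate_realization(
            cohort, config, realization_seeds[r], impact, realization_index=r
        )
        records.extend(recs)
        fractures[r] = len(recs)
        evals[r] = n_eval
        per_year[r] = py

    convergence = None
    if compute_convergence and config.n_realizations >= 2:
        conv_rng = np.random.Generator(np.random.PCG64(conv_seed))
        convergence = convergence_check(
            fractures, threshold=config.convergence_threshold, rng=conv_rng, n_boot=n_boot
        )

    return TrialResult(
        fractures_per_realization=fractures,
        n_strength_evaluations_per_realization=evals,
        per_year_counts=per_year,
        records=records,
        n_patients=len(cohort),
        config=config,
        convergence=convergence,
    )
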