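"""Side-fall impact mechanics: hip impact velocity, peak force,
soft-tissue/flooring attenuation, and the discrete fall-direction grid.

The body-floor impact is a single-degree-of-freedom mass-spring model:
the hip centre free-falls from a fixed fraction of body height, giving
an impact velocity v = sqrt(2 g h_hip) (with multiplicative lognormal
noise representing fall-dynamics variability), and the peak contact
force of the undamped spring impact is F = v * sqrt(k * m_eff), where
m_eff is the fraction of body mass effectively engaged at impact.
Trochanteric soft tissue and flooring attenuate the force
multiplicatively; attenuation can only reduce the force.  Muscle
contraction during the fall is neglected (elderly reaction times exceed
the 300-750 ms duration of an unexpected fall).

The impact direction on the femur is described by the intra-extra
rotation angle alpha in [-30, 30] deg and the abduction-adduction angle
beta in [0, 30] deg, discretised at 1 deg: 61 x 31 = 1891 equiprobable,
mutually independent directions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

GRAVITY = 9.81  # m/s^2

ALPHA_GRID = np.arange(-30, 31)  # deg, intra-extra rotation
BETA_GRID = np.arange(0, 31)  # deg, abduction-adduction
N_DIRECTIONS = ALPHA_GRID.size * BETA_GRID.size  # 1891

__all__ = [
    "ImpactParams",
    "impact_velocity",
    "peak_impact_force",
    "attenuate_force",
    "sample_fall_direction",
    "ALPHA_GRID",
    "BETA_GRID",
    "N_DIRECTIONS",
    "GRAVITY",
]


@dataclass(frozen=True)
class ImpactParams:
    """Parameters of the side-fall impact pipeline.

    hip_height_fraction : hip-centre height as a fraction of body height
    effective_mass_fraction : fraction of body mass engaged at impact
    contact_stiffness : body-floor contact stiffness, N/m
    attenuation_per_mm : fractional force reduction per mm of soft tissue
    flooring_factor : flooring/hip-protector multiplier in (0, 1]
    velocity_noise_cv : CV of the lognormal impact-velocity noise
    attenuation_floor : lower clamp of the soft-tissue factor
    """

    g: float = GRAVITY
    hip_height_fraction: float = 0.51
    effective_mass_fraction: float = 0.35
    contact_stiffness: float = 50_000.0
    attenuation_per_mm: float = 0.02
    flooring_factor: float = 1.0
    velocity_noise_cv: float = 0.1
    attenuation_floor: float = 0.3

    def __post_init__(self):
        for name in (
            "g",
            "hip_height_fraction",
            "effective_mass_fraction",
            "contact_stiffness",
            "flooring_factor",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.flooring_factor > 1:
            raise ValueError("flooring_factor must be <= 1 (attenuation, not amplification)")
        if self.attenuation_per_mm < 0 or self.velocity_noise_cv < 0:
            raise ValueError("attenuation_per_mm and velocity_noise_cv must be >= 0")
        if not 0 < self.attenuation_floor <= 1:
            raise ValueError("attenuation_floor must be in (0, 1]")


def _lognormal_factor(cv: float, rng: np.random.Generator) -> float:
    """Unit-mean lognormal multiplier with coefficient of variation cv."""
    if cv == 0:
        return 1.0
    sigma2 = np.log1p(cv**2)
    return float(rng.lognormal(mean=-sigma2 / 2, sigma=np.sqrt(sigma2)))


def impact_velocity(
    height: float, params: ImpactParams = ImpactParams(), rng: np.random.Generator = None
) -> float:
    """Hip impact velocity (m/s): free fall from the hip height plus noise."""
    if height <= 0:
        raise ValueError("height must be positive")
    v = np.sqrt(2.0 * params.g * params.hip_height_fraction * height)
    if rng is not None:
        v *= _lognormal_factor(params.velocity_noise_cv, rng)
    return float(v)


def peak_impact_force(weight: float, v: float, params: ImpactParams = ImpactParams()) -> float:
    """Peak contact force (N) of the mass-spring impact: v * sqrt(k * m_eff)."""
    if weight <= 0 or v < 0:
        raise ValueError("weight must be positive and velocity non-negative")
    m_eff = params.effective_mass_fraction * weight
    return float(v * np.sqrt(params.contact_stiffness * m_eff))


def attenuate_force(
    force: float, soft_tissue_thickness: float, params: ImpactParams = ImpactParams()
) -> float:
    """Force transmitted to the femur after soft-tissue and flooring attenuation."""
    if force < 0:
        raise ValueError("force must be non-negative")
    if soft_tissue_thickness <= 0:
        raise ValueError("soft tissue thickness must be positive")
    tissue = max(1.0 - params.attenuation_per_mm * soft_tissue_thickness, params.attenuation_floor)
    return float(force * params.flooring_factor * tissue)


def sample_fall_direction(rng: np.random.Generator) -> tuple:
    """Draw (alpha, beta) in deg, uniform and independent on the 61 x 31 grid."""
    alpha = int(rng.integers(ALPHA_GRID[0], ALPHA_GRID[-1] + 1))
    beta = int(rng.integers(BETA_GRID[0], BETA_GRID[-1] + 1))
    return alpha, beta
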