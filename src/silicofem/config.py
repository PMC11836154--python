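"""Validated run configuration (YAML or JSON, one file, six blocks)."""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from .atlas import AnthropometryParams, CohortTarget, SoftTissueParams
from .impact import ImpactParams
from .strength import SurrogateParams

__all__ = ["RunConfig", "ConfigError", "load_config", "save_config"]


class ConfigError(ValueError):
    """Invalid or unreadable configuration file."""


class _Block(BaseModel):
    model_config = ConfigDict(extra="forbid")


class CohortBlock(_Block):
    n_patients: int = Field(default=1238, ge=1)
    abmd_mean: float = Field(default=0.722, gt=0)
    abmd_sd: float = Field(default=0.096, gt=0)
    neck_to_total_ratio: float = Field(default=0.82, gt=0)
    height_mean: float = Field(default=1.60, gt=0)
    height_sd: float = Field(default=0.06, gt=0)
    weight_mean: float = Field(default=66.0, gt=0)
    weight_sd: float = Field(default=11.0, gt=0)
    corr_abmd: float = Field(default=0.4, ge=-1, le=1)
    corr_height_weight: float = Field(default=0.5, ge=-1, le=1)
    neck_abmd_mean: float = Field(default=0.56, gt=0)
    neck_abmd_sd: float = Field(default=0.08, gt=0)
    stt_intercept: float = -10.0
    stt_slope: float = Field(default=1.2, ge=0)
    stt_floor: float = Field(default=2.0, gt=0)


class FallsBlock(_Block):
    lam: float = Field(default=0.65, ge=0)


class ImpactBlock(_Block):
    hip_height_fraction: float = Field(default=0.51, gt=0)
    effective_mass_fraction: float = Field(default=0.35, gt=0)
    contact_stiffness: float = Field(default=50_000.0, gt=0)
    attenuation_per_mm: float = Field(default=0.02, ge=0)
    flooring_factor: float = Field(default=1.0, gt=0, le=1)
    velocity_noise_cv: float = Field(default=0.1, ge=0)
    attenuation_floor: float = Field(default=0.3, gt=0, le=1)


class StrengthBlock(_Block):
    c0: float = 6.3
    c1: float = 3.4
    residual_cv: float = Field(default=0.2, ge=0)
    modulation_amplitude: float = Field(default=0.2, ge=0, lt=1)


class TrialBlock(_Block):
    years: int = Field(default=3, ge=1)
    n_realizations: int = Field(default=10, ge=1)
    master_seed: int = 0


class ConvergenceBlock(_Block):
    threshold: float = Field(default=0.01, gt=0, lt=1)
    n_boot: int = Field(default=10_000, ge=10)


class FixtureBlock(_Block):
    n_train: int = Field(default=94, ge=3)
    n_features: int = Field(default=240, ge=5)
    seed: int = 0


class RunConfig(_Block):
    """Full pipeline configuration with every documented default."""

    cohort: CohortBlock = CohortBlock()
    falls: FallsBlock = FallsBlock()
    impact: ImpactBlock = ImpactBlock()
    strength: StrengthBlock = StrengthBlock()
    trial: TrialBlock = TrialBlock()
    convergence: ConvergenceBlock = ConvergenceBlock()
    fixtures: FixtureBlock = FixtureBlock()

    # -- domain-object views -------------------------------------------------
    def cohort_target(self) -> CohortTarget:
        return CohortTarget(self.cohort.n_patients, self.cohort.abmd_mean, self.cohort.abmd_sd)

    def anthropometry_params(self) -> AnthropometryParams:
        c = self.cohort
        return AnthropometryParams(
            height_mean=c.height_mean,
            height_sd=c.height_sd,
            weight_mean=c.weight_mean,
            weight_sd=c.weight_sd,
            corr_abmd=c.corr_abmd,
            corr_height_weight=c.corr_height_weight,
            neck_abmd_mean=c.neck_abmd_mean,
            neck_abmd_sd=c.neck_abmd_sd,
        )

    def soft_tissue_params(self) -> SoftTissueParams:
        c = self.cohort
        return SoftTissueParams(intercept=c.stt_intercept, slope=c.stt_slope, floor=c.stt_floor)

    def impact_params(self) -> ImpactParams:
        return ImpactParams(**self.impact.model_dump())

    def surrogate_params(self) -> SurrogateParams:
        return SurrogateParams(**self.strength.model_dump())

    def trial_config(self, master_seed: Optional[int] = None):
        from .trial import TrialConfig

        return TrialConfig(
            lam=self.falls.lam,
            years=self.trial.years,
            n_realizations=self.trial.n_realizations,
            convergence_threshold=self.convergence.threshold,
            master_seed=self.trial.master_seed if master_seed is None else master_seed,
            cohort=self.cohort_target(),
        )


def load_config(path) -> RunConfig:
    """Load and validate a YAML/JSON config; an empty file means all defaults.

    Unknown keys are rejected with an error naming the offending keys.
    """
    p = Path(path)
    if not p.exists():
        raise ConfigError(f"config file not found: {p}")
    try:
        data = yaml.safe_load(p.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse {p}: {exc}") from exc
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError(f"config root must be a mapping, got {type(data).__name__}")
    try:
        return RunConfig(**data)
    except ValidationError as exc:
        raise ConfigError(str(exc)) from exc


def save_config(config: RunConfig, path) -> None:
    """Write the config as YAML; ``load_config(save_config(c)) == c``."""
    Path(path).write_text(yaml.safe_dump(config.model_dump(), sort_keys=False))
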