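"""YAML pipeline configuration with strict validation.

Schema (all blocks optional unless a command requires them; unknown keys
are rejected everywhere):

.. code-block:: yaml

    seed: 1
    grid: {shape: [64, 64, 64], voxel_size: [0.5, 0.5, 0.5]}
    acquisition: {TR: 1500, TE: 3.7, TI: 900, flip_angle: 12,
                  r1: 3.7, T1_baseline: 1000, S0: 1000,
                  time_points: [0.5, 1, 1.5, 2, 3, 4, 5, 6, 7, 8]}
    scenarios:
      - {name: sham, n_subjects: 10, snr: 20}          # named group, or:
      - {name: custom, D_star: 3.0e-4, k_prime: 5.0e-5, n_subjects: 5,
         noise_sigma: 0.01, between_subject_cv: {D_star: 0.15}}
    analysis: {alpha: 0.2, D_free: 3.8e-4, signal_law: saturation,
               max_shift: 0, mask_snr: 3.0, k_sigma: 3.0,
               half_life_method: log-linear}
    alpha_level: 0.05
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .core import VoxelGrid
from .model import DEFAULT_ALPHA, DiffusionClearanceModel
from .phantom import GROUP_PARAMS, GroupScenario, noise_sigma_for_snr
from .pipeline import AnalysisOptions
from .signal import DEFAULT_TIME_POINTS_H, AcquisitionParams

__all__ = ["PipelineConfig", "load_config"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class GridConfig(_Strict):
    shape: tuple[int, int, int] = (64, 64, 64)
    voxel_size: tuple[float, float, float] = (0.5, 0.5, 0.5)

    def build(self) -> VoxelGrid:
        return VoxelGrid.centered(shape=self.shape, voxel_size=self.voxel_size)


class AcquisitionConfig(_Strict):
    TR: float = 1500.0
    TE: float = 3.7
    TI: float = 900.0
    flip_angle: float = 12.0
    r1: float = 3.7
    T1_baseline: float = 1000.0
    S0: float = 1000.0
    time_points: tuple[float, ...] = DEFAULT_TIME_POINTS_H

    def build(self) -> AcquisitionParams:
        return AcquisitionParams(**self.model_dump())


class ScenarioConfig(_Strict):
    name: str
    n_subjects: int = Field(default=10, ge=1)
    seed: int | None = None  # defaults to the top-level seed
    D_star: float | None = None
    k_prime: float | None = None
    Q: float = 20.0
    alpha: float = DEFAULT_ALPHA
    infusion_duration: float = 600.0
    noise_sigma: float | None = Field(default=None, ge=0)
    snr: float | None = Field(default=None, gt=0)
    between_subject_cv: dict[str, float] = Field(default_factory=dict)

    @model_validator(mode="after")
    def _check(self):
        if self.name not in GROUP_PARAMS and (self.D_star is None or self.k_prime is None):
            raise ValueError(
                f"scenario {self.name!r}: give D_star and k_prime, or use one of "
                f"the named groups {sorted(GROUP_PARAMS)}"
            )
        if self.noise_sigma is not None and self.snr is not None:
            raise ValueError("give noise_sigma or snr, not both")
        return self

    def build(self, grid: VoxelGrid, acq: AcquisitionParams, default_seed: int) -> GroupScenario:
        central = GROUP_PARAMS.get(self.name, {})
        model = DiffusionClearanceModel(
            D_star=self.D_star if self.D_star is not None else central["D_star"],
            k_prime=self.k_prime if self.k_prime is not None else central["k_prime"],
            Q=self.Q,
            alpha=self.alpha,
            infusion_duration=self.infusion_duration,
        )
        if self.snr is not None:
            noise = noise_sigma_for_snr(model, grid, acq, self.snr)
        else:
            noise = self.noise_sigma or 0.0
        return GroupScenario(
            name=self.name,
            true_params=model,
            between_subject_cv=self.between_subject_cv,
            noise_sigma=noise,
            n_subjects=self.n_subjects,
            seed=self.seed if self.seed is not None else default_seed,
        )


class AnalysisConfig(_Strict):
    alpha: float = DEFAULT_ALPHA
    D_free: float = 3.8e-4
    signal_law: str = "saturation"
    max_shift: int = Field(default=0, ge=0)
    mask_snr: float = 3.0
    k_sigma: float = 3.0
    infusion_duration: float = 600.0
    half_life_method: str = "log-linear"

    def build(self) -> AnalysisOptions:
        return AnalysisOptions(**self.model_dump())


class PipelineConfig(_Strict):
    seed: int = 0
    grid: GridConfig = Field(default_factory=GridConfig)
    acquisition: AcquisitionConfig = Field(default_factory=AcquisitionConfig)
    scenarios: list[ScenarioConfig] = Field(default_factory=list)
    analysis: AnalysisConfig = Field(default_factory=AnalysisConfig)
    alpha_level: float = Field(default=0.05, gt=0, lt=1)

    def config_hash(self) -> str:
        blob = json.dumps(self.model_dump(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def load_config(path: Path | str) -> PipelineConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    return PipelineConfig.model_validate(raw)
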