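"""Structured pipeline configuration with strict schema validation.

One YAML file carries every module's settings.  Unknown keys are rejected,
and an exact snapshot of the configuration in force is written next to
every output directory (the reproducibility contract).
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict

from .curation import CurationConfig
from .simulate import RenderParams, SimParams

__all__ = [
    "AnalysisSettings",
    "CurationSettings",
    "DetectionSettings",
    "PipelineConfig",
    "RenderSettings",
    "SimSettings",
    "load_config",
    "save_config",
]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SimSettings(_Strict):
    baseline_rate: float = 0.006
    dip_depth: float = 0.4
    recovery_width: float = 30.0
    trough_offset: float = 0.0
    g1_mean_swarmer: float = 40.0
    g1_mean_stalked: float = 12.0
    g1_dispersion: float = 0.5
    division_ratio: float = 0.45
    sep_offset_mean: float = 18.0
    sep_offset_sd: float = 5.0
    frame_interval_phase: float = 1.5
    frame_interval_fluor: float = 3.0
    area_noise_cv: float = 0.005
    rate_cv: float = 0.10
    interdivision_mean: float = 120.0
    interdivision_sd: float = 15.0
    founder_area: float = 1.8
    cell_width: float = 0.7
    stalk_visibility: float = 0.9
    swarmer_motion_um: float = 3.0
    focus_initial_sep: float = 0.5
    focus_seg_speed: float = 0.15
    n_generations: int = 3
    n_founders: int = 8

    def to_params(self, seed: int) -> SimParams:
        fields = self.model_dump(exclude={"n_generations", "n_founders"})
        return SimParams(seed=seed, **fields)


class RenderSettings(_Strict):
    pixel_size: float = 0.065
    psf_sigma: float = 1.3
    background_level: float = 200.0
    focus_amplitude: float = 300.0
    noise_model: Literal["poisson", "gaussian", "none"] = "poisson"
    image_shape: tuple[int, int] = (64, 64)

    def to_params(self) -> RenderParams:
        return RenderParams(**self.model_dump())


class DetectionSettings(_Strict):
    psf_sigma: float = 1.3
    min_separation: float = 3.0
    snr_threshold: float = 5.0


class AnalysisSettings(_Strict):
    birth_definition: Literal["cytokinesis", "separation"] = "cytokinesis"
    smooth_window: int = 12
    n_bins: int = 30
    n_boot: int = 1000
    alpha: float = 0.05
    motion_threshold: float = 1.0


class CurationSettings(_Strict):
    min_duration: float = 30.0
    min_area_increase: float = 0.61
    rate_upper: float = 0.015
    rate_lower: float = -0.0025
    max_birth_time: Optional[float] = None
    require_complete_lineage: bool = True
    drop_uncertain: bool = True
    manual_exclusions: tuple[str, ...] = ()

    def to_config(self) -> CurationConfig:
        return CurationConfig(**self.model_dump())


class PipelineConfig(_Strict):
    seed: int = 0
    simulate: SimSettings = SimSettings()
    render: RenderSettings = RenderSettings()
    detection: DetectionSettings = DetectionSettings()
    analysis: AnalysisSettings = AnalysisSettings()
    curation: CurationSettings = CurationSettings()


def load_config(path: str | Path | None) -> PipelineConfig:
    """Load a YAML config; ``None`` yields the defaults."""
    if path is None:
        return PipelineConfig()
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    return PipelineConfig.model_validate(data)


def save_config(config: PipelineConfig, path: str | Path) -> None:
    """Write the exact configuration snapshot as YAML."""
    data = config.model_dump(mode="json")
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(data, fh, sort_keys=True)
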