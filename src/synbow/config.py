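"""Run configuration: validated JSON/YAML blocks for end-to-end runs."""

from __future__ import annotations

import json
from pathlib import Path

import yaml
from pydantic import BaseModel, Field, field_validator

from .neuropil import SizeDistribution
from .optics import OperatingPoint, PSFSpec


class NeuropilConfig(BaseModel):
    extents_um: tuple[float, float, float] = (8.0, 8.0, 4.0)
    voxel_size_um: tuple[float, float, float] = (0.05, 0.05, 0.05)
    density_per_um3: float = Field(1.85, ge=0)
    mean_area_um2: float = 0.05
    min_area_um2: float = 0.005
    max_area_um2: float = 0.4
    n_pre_neurons: int = Field(256, ge=1)
    n_post_neurons: int = Field(30, ge=1)
    n_channels_pre: int = Field(1, ge=0)
    n_channels_post: int = Field(1, ge=0)

    def size_dist(self) -> SizeDistribution:
        return SizeDistribution(
            self.mean_area_um2, self.min_area_um2, self.max_area_um2)


class OperatingPointConfig(BaseModel):
    f: float = Field(0.5, ge=0, le=1)
    c_per_um2: float = Field(750.0, ge=0)
    b_uM: float = Field(0.1, ge=0)
    h_photons: float = Field(1000.0, ge=0)

    def build(self) -> OperatingPoint:
        return OperatingPoint(self.f, self.c_per_um2, self.b_uM, self.h_photons)


class InstrumentConfig(BaseModel):
    name: str = "SIM"
    d_xy_um: float = Field(0.1, gt=0)
    d_z_um: float = Field(0.1, gt=0)

    def psf(self) -> PSFSpec:
        return PSFSpec(self.d_xy_um, self.d_z_um)


class DetectionConfig(BaseModel):
    n_levels: int = Field(100, ge=2)
    t_v: int = Field(1, ge=1)
    noise: bool = True
    fp_mode: str = "blend_sets"

    @field_validator("fp_mode")
    @classmethod
    def _check_mode(cls, v):
        if v not in ("blend_sets", "clusters", "voxels"):
            raise ValueError(f"unknown fp_mode {v!r}")
        return v


class RunConfig(BaseModel):
    """Top-level run configuration; all stochastic stages derive from seed."""

    neuropil: NeuropilConfig = NeuropilConfig()
    operating_point: OperatingPointConfig = OperatingPointConfig()
    instrument: InstrumentConfig = InstrumentConfig()
    detection: DetectionConfig = DetectionConfig()
    seed: int = 0
    out_dir: str = "synbow_out"


def load_config(path: str | Path) -> RunConfig:
    path = Path(path)
    text = path.read_text()
    data = yaml.safe_load(text) if path.suffix in (".yml", ".yaml") \
        else json.loads(text)
    return RunConfig.model_validate(data)


def save_config(cfg: RunConfig, path: str | Path):
    Path(path).write_text(json.dumps(cfg.model_dump(), indent=2))
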