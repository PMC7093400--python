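"""Validated run configuration (YAML-backed) and model construction.

Defaults follow the clinical protocol wherever it states a value: 10-50 Hz
band, 100-ms baseline windows, 100 baselines, 1,000 permutation
randomizations, 5-ms dipole stepping, GOF > 70%, 50-500 nAm moment
acceptance, 34 sublobar regions, and an initial 0.05 significance level.
Unknown keys are rejected.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field

from .cds import DEFAULT_LADDER, CdsConfig
from .head_model import (
    LeadField,
    SensorArray,
    SourceGrid,
    SphereModel,
    build_sensor_array,
    build_source_grid,
    compute_leadfield,
)


class ModelSection(BaseModel):
    model_config = ConfigDict(extra="forbid")

    sphere_radius_m: float = 0.09
    grid_spacing_m: float = 0.007
    n_regions: int = 34
    grid_margin_m: float = 0.005
    n_channels: int = 160
    helmet_radius_m: float = 0.12
    cap_fraction: float = 0.55
    baseline_m: float = 0.05


class InverseSection(BaseModel):
    model_config = ConfigDict(extra="forbid")

    snr: float = 3.0
    shrinkage: float = 0.1


class CdsSection(BaseModel):
    model_config = ConfigDict(extra="forbid")

    low_hz: float = 10.0
    high_hz: float = 50.0
    n_perm: int = 1000
    ladder: tuple[float, ...] = DEFAULT_LADDER
    guard_s: float = 1.0
    seed: int = 0


class EcdSection(BaseModel):
    model_config = ConfigDict(extra="forbid")

    step_s: float = 0.005
    gof_min_pct: float = 70.0
    q_min_nam: float = 50.0
    q_max_nam: float = 500.0
    scatter_fraction: float = 0.25


class SimSection(BaseModel):
    model_config = ConfigDict(extra="forbid")

    sr: float = 5000.0
    session_s: float = 240.0
    n_sessions: int = 5
    n_ied: int = 10
    spike_duration_s: float = 0.08
    moment_nAm: float = 200.0
    snr: float | None = 4.0
    n_noise_dipoles: int = 200
    n_bl: int = 100


class RunConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    model: ModelSection = Field(default_factory=ModelSection)
    inverse: InverseSection = Field(default_factory=InverseSection)
    cds: CdsSection = Field(default_factory=CdsSection)
    ecd: EcdSection = Field(default_factory=EcdSection)
    sim: SimSection = Field(default_factory=SimSection)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.model_validate(data)

    def cds_config(self, seed: int | None = None) -> CdsConfig:
        return CdsConfig(
            low_hz=self.cds.low_hz,
            high_hz=self.cds.high_hz,
            snr=self.inverse.snr,
            shrinkage=self.inverse.shrinkage,
            n_perm=self.cds.n_perm,
            ladder=tuple(self.cds.ladder),
            seed=self.cds.seed if seed is None else seed,
        )

    def digest(self) -> str:
        payload = json.dumps(self.model_dump(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def build_model(
    config: RunConfig,
) -> tuple[SensorArray, SphereModel, SourceGrid, LeadField]:
    """Construct sensors, sphere, source grid, and lead field from config."""
    m = config.model
    sensors = build_sensor_array(
        n_channels=m.n_channels,
        helmet_radius=m.helmet_radius_m,
        cap_fraction=m.cap_fraction,
        baseline=m.baseline_m,
    )
    sphere = SphereModel(center=np.zeros(3), radius=m.sphere_radius_m)
    grid = build_source_grid(
        sphere, spacing=m.grid_spacing_m, n_regions=m.n_regions, margin=m.grid_margin_m
    )
    leadfield = compute_leadfield(grid, sensors, sphere)
    return sensors, sphere, grid, leadfield


def write_manifest(out_dir: str | Path, config: RunConfig, seed: int) -> Path:
    """Record config hash and seed alongside any command's outputs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"config_sha256_16": config.digest(), "seed": seed}
    path = out / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2))
    return path
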