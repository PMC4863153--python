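"""Validated run configuration (YAML or JSON) for the CLI pipelines.

A :class:`RunConfig` bundles beam, phantom source, transport, biology and
monitoring settings.  Unknown keys are rejected with their key path; every
run writes a resolved-config snapshot next to its outputs.  All physical
units are explicit in the key names (``energy_MeV_u``, ``spacing_mm``).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from .biodose import PhotonReference
from .materials import VoxelPhantom, make_slab_phantom
from .stopping import PROJECTILES
from .transport import BeamSpec, TransportConfig

SCHEMA_VERSION = 1


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class BeamConfig(_Strict):
    particle: Literal["proton", "helium", "carbon", "oxygen"] = "proton"
    energy_MeV_u: float = Field(gt=0)
    n_primaries: int = Field(ge=1)
    energy_sigma_MeV_u: float = Field(default=0.0, ge=0)
    spot_sigma_x_mm: float = Field(default=0.0, ge=0)
    spot_sigma_y_mm: float = Field(default=0.0, ge=0)
    position_mm: tuple[float, float, float] = (20.0, 20.0, 0.0)
    direction: tuple[float, float, float] = (0.0, 0.0, 1.0)

    def to_beam(self, n_primaries: int | None = None) -> BeamSpec:
        import numpy as np
        d = np.asarray(self.direction, dtype=float)
        d = d / np.linalg.norm(d)
        return BeamSpec(
            projectile=PROJECTILES[self.particle],
            nominal_energy=self.energy_MeV_u,
            n_primaries=n_primaries or self.n_primaries,
            energy_sigma=self.energy_sigma_MeV_u,
            spot_sigma_x=self.spot_sigma_x_mm,
            spot_sigma_y=self.spot_sigma_y_mm,
            position=self.position_mm,
            direction=tuple(d),
        )


class PhantomLayer(_Strict):
    material: str
    thickness_mm: float = Field(gt=0)


class PhantomConfig(_Strict):
    kind: Literal["water_slab", "layered", "file"] = "water_slab"
    length_mm: float = Field(default=300.0, gt=0)
    cross_section_mm: float = Field(default=40.0, gt=0)
    spacing_mm: float = Field(default=1.0, gt=0)
    layers: Optional[list[PhantomLayer]] = None
    path: Optional[str] = None

    def build(self) -> VoxelPhantom:
        if self.kind == "water_slab":
            return make_slab_phantom([("water", self.length_mm)],
                                     self.cross_section_mm,
                                     self.spacing_mm)
        if self.kind == "layered":
            if not self.layers:
                raise ValueError("layered phantom requires 'layers'")
            return make_slab_phantom(
                [(la.material, la.thickness_mm) for la in self.layers],
                self.cross_section_mm, self.spacing_mm,
            )
        if not self.path:
            raise ValueError("file phantom requires 'path'")
        from .gridio import load_hu_phantom
        return load_hu_phantom(Path(self.path).with_suffix(""))


class TransportSettings(_Strict):
    max_fractional_energy_loss_per_step: float = Field(default=0.02,
                                                       gt=0, le=0.05)
    delta_threshold_MeV: float = Field(default=0.1, ge=1e-3)
    straggling_model: Literal["none", "gaussian"] = "gaussian"
    mcs_model: Literal["none", "highland"] = "highland"
    nuclear_model: Literal["none", "attenuation",
                           "attenuation+tail"] = "attenuation+tail"
    tail_local_fraction: float = Field(default=0.6, ge=0, le=1)
    tail_mfp_cm: float = Field(default=2.0, gt=0)
    tail_forward_dose_fraction: float = Field(default=0.3, ge=0, le=1)
    rng_seed: int = 0
    n_batches: int = Field(default=10, ge=1)

    def to_transport(self, seed: int | None = None) -> TransportConfig:
        return TransportConfig(
            max_fractional_energy_loss_per_step=(
                self.max_fractional_energy_loss_per_step),
            delta_threshold=self.delta_threshold_MeV,
            straggling_model=self.straggling_model,
            mcs_model=self.mcs_model,
            nuclear_model=self.nuclear_model,
            tail_params=(self.tail_local_fraction, self.tail_mfp_cm,
                         self.tail_forward_dose_fraction),
            rng_seed=self.rng_seed if seed is None else seed,
            n_batches=self.n_batches,
        )


class BiologyConfig(_Strict):
    mode: Literal["physical", "constant_rbe", "lq_mixed"] = "physical"
    lq_table_csv: Optional[str] = None
    species: Optional[str] = None
    photon_alpha_Gy: float = Field(default=0.1, gt=0)
    photon_beta_Gy2: float = Field(default=0.05, gt=0)
    prescription_Gy_RBE: float = Field(default=3.0, gt=0)
    target_depth_mm: tuple[float, float] = (60.0, 120.0)

    def photon_reference(self) -> PhotonReference:
        return PhotonReference(self.photon_alpha_Gy, self.photon_beta_Gy2)


class MonitorConfig(_Strict):
    cross_section_csvs: Optional[list[str]] = None
    detector_radius_mm: float = Field(default=300.0, gt=0)
    detector_axial_mm: float = Field(default=200.0, gt=0)
    opening_angle_deg: float = Field(default=180.0, ge=0, le=180)
    energy_window_keV: tuple[float, float] = (350.0, 650.0)
    t_start_s: float = Field(default=120.0, ge=0)
    t_acq_s: float = Field(default=300.0, ge=0)


class RunConfig(_Strict):
    schema_version: int = SCHEMA_VERSION
    beam: BeamConfig
    phantom: PhantomConfig = PhantomConfig()
    transport: TransportSettings = TransportSettings()
    biology: BiologyConfig = BiologyConfig()
    monitor: Optional[MonitorConfig] = None
    output_dir: str = "out"

    @field_validator("schema_version")
    @classmethod
    def _check_version(cls, v: int) -> int:
        if v != SCHEMA_VERSION:
            raise ValueError(f"unsupported schema_version {v}; "
                             f"expected {SCHEMA_VERSION}")
        return v


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML/JSON run configuration."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    data = yaml.safe_load(path.read_text())
    if not isinstance(data, dict):
        raise ValueError(f"{path}: top level must be a mapping")
    return RunConfig.model_validate(data)


def dump_config(config: RunConfig, path: str | Path) -> None:
    """Write the fully resolved config snapshot as YAML."""
    Path(path).write_text(
        yaml.safe_dump(json.loads(config.model_dump_json()),
                       sort_keys=False)
    )
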