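"""Validated simulation configuration (YAML round-trip).

Every run is described by a :class:`SimConfig`; the exact resolved config
(all defaults filled in) is archived beside the run outputs so that any
result can be regenerated from the archive alone.
"""
from __future__ import annotations

from pathlib import Path
from typing import Literal, Optional, Union

import yaml
from pydantic import BaseModel, Field, model_validator

__all__ = ["Geometry1D", "Geometry3D", "TriggerConfig", "Numerics",
           "SimConfig", "load_config", "save_config"]


class Geometry1D(BaseModel):
    kind: Literal["interval"] = "interval"
    length_mm: float = Field(gt=0)
    dx_um: float = Field(default=10.0, gt=0)
    bc: Literal["noflux", "periodic"] = "noflux"

    @model_validator(mode="after")
    def _commensurate(self):
        n = self.length_mm * 1000.0 / self.dx_um
        if abs(n - round(n)) > 1e-9 * max(n, 1.0):
            raise ValueError(f"length {self.length_mm} mm is not an integer "
                             f"number of cells of {self.dx_um} um")
        return self


class Geometry3D(BaseModel):
    kind: Literal["sphere", "prolate", "tet_ball"]
    diameter_mm: float = Field(default=1.0, gt=0)
    minor_axis_mm: Optional[float] = Field(default=None, gt=0)  # prolate only
    spacing_um: float = Field(default=20.0, gt=0)

    @model_validator(mode="after")
    def _spacing_sane(self):
        smallest = self.minor_axis_mm or self.diameter_mm
        if self.spacing_um >= smallest * 1000.0 / 2.0:
            raise ValueError(f"target spacing {self.spacing_um} um is not "
                             f"small compared to the geometry "
                             f"({smallest} mm)")
        return self

    @property
    def length_mm(self) -> float:
        """Extent along the central (fertilization) axis."""
        return self.diameter_mm


class TriggerConfig(BaseModel):
    kind: Literal["wave", "spreading", "instantaneous"]
    speed_mm_min: Optional[float] = Field(default=None, gt=0)
    start_time_min: float = 0.0
    threshold_factor: float = Field(default=4.0, gt=1.0)
    active_fraction: float = Field(default=0.1, ge=0.0, le=1.0)

    @model_validator(mode="after")
    def _speed_required(self):
        if self.kind == "wave" and self.speed_mm_min is None:
            raise ValueError("trigger kind 'wave' requires speed_mm_min")
        return self


class Numerics(BaseModel):
    dt_s: float = Field(default=0.1, gt=0)
    method: Literal["crank_nicolson", "ftcs"] = "crank_nicolson"
    linsolve_tol: float = Field(default=1e-10, gt=0)
    arrest_residual_tol: float = Field(default=1e-8, gt=0)
    rtol: float = Field(default=1e-8, gt=0)
    atol: float = Field(default=1e-10, gt=0)


class SimConfig(BaseModel):
    """Full description of one reaction-diffusion run."""

    geometry: Union[Geometry1D, Geometry3D]
    trigger: TriggerConfig
    numerics: Numerics = Numerics()
    t_end_min: float = Field(gt=0)
    output_every_min: float = Field(default=0.25, gt=0)
    record_species: list[str] = ["cycB_cdk1_YpTp"]
    params_overrides: dict[str, float] = {}
    params_file: Optional[str] = None
    cellularize: bool = False
    output_dir: Optional[str] = None
    run_id: str = "run"

    def resolved_params(self):
        from .params import default_params, load_params
        p = load_params(self.params_file) if self.params_file else default_params()
        return p.replace(**self.params_overrides) if self.params_overrides else p


def load_config(path: str | Path) -> SimConfig:
    with open(path) as fh:
        return SimConfig.model_validate(yaml.safe_load(fh))


def save_config(config: SimConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.model_dump(mode="json"), fh, sort_keys=False)
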