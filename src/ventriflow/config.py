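"""Configuration schema, validation and reproducibility plumbing.

A run is described by a single YAML/JSON document with geometry / waveform /
fluid / leaflet / coupling / output sections.  Every physical default is the
reference value of the model (blood density 1050 kg/m^3, viscosity 3.5 mPa s,
heart rate 62 beats/min, leaflet travel 25-85 deg, ...), so an empty document
is a complete, runnable configuration.  Field names carry explicit unit
suffixes to prevent silent unit errors.  Unknown keys are rejected with the
offending path; every run directory receives the fully resolved config echo.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import List, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

from .fluid import Grid
from .geometry import VentricleGeometry
from .leaflets import LeafletState, make_leaflets
from .waveform import DiastoleSchedule, cycle_period

SCHEMA_VERSION = "1"

__all__ = [
    "SimulationConfig",
    "ConfigError",
    "validate_config",
    "emit_config",
    "config_hash",
]


class ConfigError(ValueError):
    """Invalid configuration; message lists field paths and admissible ranges."""


class _Section(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class GeometryConfig(_Section):
    alpha: float = Field(2.0, gt=0)
    r_trunc_mm: float = Field(18.0, gt=0)
    c_min_mm: float = Field(38.0, gt=0)
    c_max_mm: float = Field(50.0, gt=0)
    v_total_min_ml: float = Field(64.0, gt=0)
    d_inlet_mm: float = Field(25.0, gt=0)
    d_outlet_mm: float = Field(20.8, gt=0)
    orifice_angle_deg: float = Field(140.0, gt=90.0, lt=180.0)
    inlet_tube_length_mm: float = Field(45.0, gt=0)
    outlet_tube_length_mm: float = Field(35.0, gt=0)
    chamber_height_mm: float = Field(4.0, gt=0)
    resolution_mm: float = Field(1.0, gt=0)

    @model_validator(mode="after")
    def _ranges(self):
        if self.c_min_mm >= self.c_max_mm:
            raise ValueError("geometry.c_min_mm must be < geometry.c_max_mm")
        if self.r_trunc_mm >= self.c_min_mm / self.alpha:
            raise ValueError(
                "geometry.r_trunc_mm must be < c_min_mm/alpha "
                f"({self.c_min_mm / self.alpha:.3f} mm)"
            )
        return self

    def build(self) -> VentricleGeometry:
        return VentricleGeometry(
            alpha=self.alpha,
            r_trunc=self.r_trunc_mm,
            c_min=self.c_min_mm,
            c_max=self.c_max_mm,
            v_total_min=self.v_total_min_ml,
            d_inlet=self.d_inlet_mm,
            d_outlet=self.d_outlet_mm,
            orifice_angle=self.orifice_angle_deg,
            inlet_tube_length=self.inlet_tube_length_mm,
            outlet_tube_length=self.outlet_tube_length_mm,
            chamber_height=self.chamber_height_mm,
        )


class WaveformConfig(_Section):
    heart_rate_bpm: float = Field(62.0, gt=0)
    v_peak_E_m_s: float = Field(0.65, gt=0)
    v_peak_A_m_s: float = Field(0.37, gt=0)
    e_end_tstar: float = Field(0.33, gt=0, le=1)
    diastasis_end_tstar: float = Field(0.43, gt=0, le=1)
    a_end_tstar: float = Field(0.65, gt=0, le=1)
    ea_volume_ratio: float = Field(2.6, gt=0)

    @model_validator(mode="after")
    def _ordered(self):
        if not (self.e_end_tstar <= self.diastasis_end_tstar <= self.a_end_tstar):
            raise ValueError(
                "waveform phase fractions must be ordered: "
                "e_end_tstar <= diastasis_end_tstar <= a_end_tstar"
            )
        return self

    @property
    def period_s(self) -> float:
        return cycle_period(self.heart_rate_bpm)

    def build(self) -> DiastoleSchedule:
        return DiastoleSchedule(
            heart_rate=self.heart_rate_bpm,
            v_peak_E=self.v_peak_E_m_s,
            v_peak_A=self.v_peak_A_m_s,
            e_end=self.e_end_tstar,
            diastasis_end=self.diastasis_end_tstar,
            a_end=self.a_end_tstar,
            ea_volume_ratio=self.ea_volume_ratio,
        )


class FluidConfig(_Section):
    rho_kg_m3: float = Field(1050.0, gt=0)
    mu_pa_s: float = Field(3.5e-3, gt=0)
    nx: int = Field(96, ge=16)
    ny: int = Field(168, ge=16)
    h_mm: float = Field(0.9375, gt=0)
    x0_mm: float = -45.0
    y0_mm: float = -97.5
    dt_ms: float = Field(0.484, gt=0)
    cfl_limit: float = Field(0.7, gt=0, le=1)
    penalization_eta_s: float = Field(1e-4, gt=0)
    outlet_pressure_mmHg: float = 110.0
    adaptive_substep: bool = True
    max_substeps: int = Field(16, ge=1)

    def build_grid(self) -> Grid:
        return Grid(
            nx=self.nx, ny=self.ny, h=self.h_mm * 1e-3,
            x0=self.x0_mm * 1e-3, y0=self.y0_mm * 1e-3,
        )


class LeafletConfig(_Section):
    chord_mm: float = Field(9.5, gt=0)
    thickness_mm: float = Field(0.8, gt=0)
    pivot_offset_mm: float = Field(2.5, ge=0)
    density_kg_m3: float = Field(2000.0, gt=0)
    theta_min_deg: float = Field(25.0, ge=0, lt=90)
    theta_max_deg: float = Field(85.0, gt=0, le=90)
    theta0_deg: float = 25.0
    pivot_y_mm: float = 9.0
    pivot_half_separation_mm: float = Field(6.5, gt=0)
    restitution: float = Field(0.0, ge=0, le=1)

    @model_validator(mode="after")
    def _travel(self):
        if self.theta_min_deg >= self.theta_max_deg:
            raise ValueError("leaflet.theta_min_deg must be < theta_max_deg")
        if not (self.theta_min_deg <= self.theta0_deg <= self.theta_max_deg):
            raise ValueError("leaflet.theta0_deg must lie within the travel limits")
        if self.pivot_offset_mm >= self.chord_mm:
            raise ValueError("leaflet.pivot_offset_mm must be < chord_mm")
        return self

    def build(self, geom: VentricleGeometry) -> list[LeafletState]:
        return make_leaflets(
            mitral_center_x=geom.mitral_center_x,
            pivot_y=self.pivot_y_mm,
            pivot_half_separation=self.pivot_half_separation_mm,
            chord=self.chord_mm,
            thickness=self.thickness_mm,
            pivot_offset=self.pivot_offset_mm,
            density=self.density_kg_m3,
            theta=self.theta0_deg,
            theta_min=self.theta_min_deg,
            theta_max=self.theta_max_deg,
            restitution=self.restitution,
        )


class CouplingConfig(_Section):
    tol_rel: float = Field(1e-3, gt=0)
    max_iters: int = Field(20, ge=1)
    omega_init: float = Field(0.5, gt=0, le=1)
    omega_min: float = Field(0.05, gt=0)
    omega_max: float = Field(1.0, le=1)
    torque_samples: int = Field(40, ge=4)
    divergence_factor: float = Field(1e3, gt=1)


class OutputConfig(_Section):
    snapshot_t_stars: List[float] = Field(
        default_factory=lambda: [0.05, 0.125, 0.2, 0.25, 0.325, 0.45, 0.55, 0.6]
    )
    trace_stride: int = Field(1, ge=1)
    end_tstar: Optional[float] = None  # default: end of diastole (waveform.a_end)


class SimulationConfig(_Section):
    schema_version: str = SCHEMA_VERSION
    geometry: GeometryConfig = Field(default_factory=GeometryConfig)
    waveform: WaveformConfig = Field(default_factory=WaveformConfig)
    fluid: FluidConfig = Field(default_factory=FluidConfig)
    leaflet: LeafletConfig = Field(default_factory=LeafletConfig)
    coupling: CouplingConfig = Field(default_factory=CouplingConfig)
    output: OutputConfig = Field(default_factory=OutputConfig)


def _format_validation_error(exc: ValidationError) -> str:
    lines = []
    for err in exc.errors():
        path = ".".join(str(p) for p in err["loc"])
        lines.append(f"{path}: {err['msg']} (got {err.get('input')!r})")
    return "invalid configuration:\n  " + "\n  ".join(lines)


def validate_config(document=None) -> SimulationConfig:
    """Resolve and range-check a configuration document.

    ``document`` may be None/{} (all defaults), a mapping, a YAML/JSON string,
    or a path to a YAML/JSON file.  Unknown keys are rejected with their path.
    """
    if document is None:
        document = {}
    if isinstance(document, SimulationConfig):
        return document
    if isinstance(document, (str, Path)):
        p = Path(document)
        if isinstance(document, Path) or (len(str(document)) < 4096 and p.is_file()):
            text = p.read_text()
        else:
            text = str(document)
        document = yaml.safe_load(text) or {}
    if not isinstance(document, dict):
        raise ConfigError(f"configuration root must be a mapping, got {type(document).__name__}")
    try:
        return SimulationConfig(**document)
    except ValidationError as exc:
        raise ConfigError(_format_validation_error(exc)) from exc


def emit_config(config: SimulationConfig) -> dict:
    """Fully-resolved plain-dict echo of a config (defaults expanded)."""
    return json.loads(config.model_dump_json())


def config_hash(config: SimulationConfig) -> str:
    """Content hash of the resolved configuration (run provenance)."""
    blob = json.dumps(emit_config(config), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]
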