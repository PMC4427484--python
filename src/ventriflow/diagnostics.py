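"""Flow readouts: out-of-plane vorticity, circulation, probe pressure traces.

Under the package's coordinate convention (x posterior, y apex-to-base,
anterior at x < 0) a clockwise-rotating vortex carries negative out-of-plane
vorticity, so the dominant anterior vortex of diastolic filling shows up as
negative circulation over the anterior half of the cavity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fluid import FlowField, SolidMasks, fill_solid_pressure
from .leaflets import _bilinear

logger = logging.getLogger(__name__)

__all__ = [
    "DiagnosticSeries",
    "vorticity",
    "pressure_difference",
    "anterior_circulation",
    "export_snapshots",
]


def vorticity(flow: FlowField, masks: SolidMasks | None = None) -> np.ndarray:
    """Out-of-plane vorticity dv/dx - du/dy at grid nodes, (nx+1, ny+1), 1/s.

    Centred differences of the staggered components land exactly on cell
    corners.  Border nodes are zero; nodes touching a solid cell are NaN when
    masks are given.
    """
    g = flow.grid
    u, v, h = flow.u, flow.v, g.h
    om = np.zeros((g.nx + 1, g.ny + 1))
    om[1:-1, 1:-1] = (v[1:, 1:-1] - v[:-1, 1:-1]) / h - (u[1:-1, 1:] - u[1:-1, :-1]) / h
    if masks is not None:
        solid = masks.solid_cells
        sp = np.pad(solid, 1, constant_values=True)
        # node (i, j) touches cells (i-1..i, j-1..j)
        node_solid = sp[:-1, :-1] | sp[1:, :-1] | sp[:-1, 1:] | sp[1:, 1:]
        om[node_solid] = np.nan
    return om


def pressure_difference(
    flow: FlowField,
    probes: tuple[np.ndarray, np.ndarray],
    masks: SolidMasks | None = None,
) -> float:
    """P_inlet - P_apex (Pa) by bilinear sampling of the gauge pressure.

    A probe landing in a solid cell falls back to the nearest fluid value
    (the pressure array is extended into solids before sampling); the
    fallback is logged.
    """
    inlet_pt, apex_pt = (np.asarray(p, float) for p in probes)
    g = flow.grid
    fluid = masks.fluid_cells if masks is not None else np.ones_like(flow.p, bool)
    if masks is not None:
        for name, pt in (("inlet", inlet_pt), ("apex", apex_pt)):
            i = int(np.clip((pt[0] - g.x0) / g.h, 0, g.nx - 1))
            j = int(np.clip((pt[1] - g.y0) / g.h, 0, g.ny - 1))
            if not fluid[i, j]:
                logger.debug("probe %s at %s inside solid; nearest-fluid fallback", name, pt)
    pf = fill_solid_pressure(flow.p, fluid)
    pts = np.vstack([inlet_pt, apex_pt])
    vals = _bilinear(pf, g, pts)
    return float(vals[0] - vals[1])


def anterior_circulation(
    flow: FlowField,
    region: np.ndarray | tuple[float, float, float, float],
    masks: SolidMasks | None = None,
) -> float:
    """Integral of the out-of-plane vorticity over a region, m^2/s.

    ``region`` is either a boolean node mask (nx+1, ny+1) or a bounding box
    (xmin, xmax, ymin, ymax) in metres; a clockwise vortex gives a negative
    value.  Solid-touching nodes are excluded.
    """
    g = flow.grid
    om = vorticity(flow, masks)
    if isinstance(region, np.ndarray):
        mask = region
    else:
        xmin, xmax, ymin, ymax = region
        XN, YN = np.meshgrid(g.xu, g.yv, indexing="ij")
        mask = (XN >= xmin) & (XN <= xmax) & (YN >= ymin) & (YN <= ymax)
    if not mask.any():
        raise ValueError("empty circulation region")
    vals = om[mask]
    return float(np.nansum(vals) * g.h**2)


@dataclass
class DiagnosticSeries:
    """Time-indexed run diagnostics plus field snapshots at requested T*."""

    t_star: np.ndarray = field(default_factory=lambda: np.empty(0))
    t_s: np.ndarray = field(default_factory=lambda: np.empty(0))
    delta_p: np.ndarray = field(default_factory=lambda: np.empty(0))
    theta: dict = field(default_factory=dict)          # label -> array (deg)
    omega: dict = field(default_factory=dict)          # label -> array (rad/s)
    circulation_anterior: np.ndarray = field(default_factory=lambda: np.empty(0))
    c_mm: np.ndarray = field(default_factory=lambda: np.empty(0))
    volume_ml: np.ndarray = field(default_factory=lambda: np.empty(0))
    v_inlet: np.ndarray = field(default_factory=lambda: np.empty(0))
    snapshots: dict = field(default_factory=dict)      # T* -> dict of arrays
    impacts: dict = field(default_factory=dict)        # label -> [(theta, rad/s)]
    fsi_iterations: np.ndarray = field(default_factory=lambda: np.empty(0, int))
    cfl_history: np.ndarray = field(default_factory=lambda: np.empty(0))
    mass_residual: np.ndarray = field(default_factory=lambda: np.empty(0))
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ts = np.asarray(self.t_star)
        if ts.size and not np.all(np.diff(ts) > 0):
            raise ValueError("t_star must be strictly increasing")

    def to_dataframe(self) -> pd.DataFrame:
        cols = {
            "t_s": self.t_s,
            "T_star": self.t_star,
            "delta_p_Pa": self.delta_p,
            "circulation_anterior_m2_s": self.circulation_anterior,
            "c_mm": self.c_mm,
            "V_ml": self.volume_ml,
            "v_inlet_m_s": self.v_inlet,
            "fsi_iterations": self.fsi_iterations,
            "cfl": self.cfl_history,
        }
        for label in self.theta:
            cols[f"theta_{label}_deg"] = self.theta[label]
            cols[f"omega_{label}_rad_s"] = self.omega[label]
        n = len(self.t_star)
        return pd.DataFrame({k: v for k, v in cols.items() if len(v) == n})


def snapshot_fields(flow: FlowField, masks: SolidMasks) -> dict:
    """Cell-centred field bundle stored for a snapshot."""
    g = flow.grid
    uc = 0.5 * (flow.u[:-1, :] + flow.u[1:, :])
    vc = 0.5 * (flow.v[:, :-1] + flow.v[:, 1:])
    om = vorticity(flow)
    om_c = 0.25 * (om[:-1, :-1] + om[1:, :-1] + om[:-1, 1:] + om[1:, 1:])
    return {
        "u": uc,
        "v": vc,
        "p": flow.p.copy(),
        "vorticity": om_c,
        "solid_mask": masks.solid_cells.astype(np.int8),
    }


def export_snapshots(series: DiagnosticSeries, t_star_list, outdir) -> list:
    """Write the stored snapshots nearest to each requested T* as VTK files."""
    from .io import write_vtk_structured
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    have = sorted(series.snapshots)
    written = []
    if len(t_star_list) == 0:
        return written
    if not have:
        raise ValueError("run stored no snapshots")
    for ts in t_star_list:
        if ts < min(have) - 0.05 or ts > max(have) + 0.05:
            raise ValueError(f"requested T*={ts} outside the run window")
        nearest = min(have, key=lambda s: abs(s - ts))
        path = outdir / f"snapshot_tstar_{ts:.3f}.vtk"
        snap = series.snapshots[nearest]
        write_vtk_structured(path, series.meta["grid"], snap)
        written.append(path)
    return written
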