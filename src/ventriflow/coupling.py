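"""Partitioned fluid-leaflet coupling with Aitken relaxation, and the run loop.

Within each time step the flow and the two leaflet rotation equations are
iterated Gauss-Seidel fashion: advance tentative leaflet angles with the
current angular accelerations, rasterize, advance the flow over the step,
evaluate the fluid torques, and under-relax the accelerations,

    theta_ddot^(k+1) = theta_ddot^(k) + omega^(k) (M^(k)/I - theta_ddot^(k)),

until the acceleration residual |M/I - theta_ddot| falls below tolerance for
both leaflets.  The scalar relaxation factor is adapted per leaflet by the
Aitken delta-squared rule from successive residuals, which handles the strong
added-mass feedback of a light leaflet in blood (the effective fluid inertia
exceeds the structural one several-fold, so the unrelaxed iteration would
diverge).  Leaflets pinned at a travel limit with the torque pressing into
the stop are treated as converged constraints (zero acceleration).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import shapely

from . import fluid as fl
from .config import SimulationConfig, config_hash, emit_config, validate_config
from .diagnostics import DiagnosticSeries, anterior_circulation, pressure_difference, snapshot_fields
from .fluid import FlowField, SolidMasks, WallRaster, rasterize_leaflets, step
from .geometry import midplane_section, wall_kinematics, _s_term
from .leaflets import LeafletState, compute_torque, enforce_travel_limits
from .waveform import axis_trajectory, build_inflow

__all__ = [
    "CouplingState",
    "FsiParams",
    "relaxed_update",
    "aitken_omega",
    "fsi_timestep",
    "run_diastole",
]


@dataclass
class CouplingState:
    """FSI iteration bookkeeping; omega and residual history are per leaflet."""

    omega: np.ndarray = field(default_factory=lambda: np.array([0.5, 0.5]))
    omega_min: float = 0.05
    omega_max: float = 1.0
    tol_rel: float = 1e-3
    max_iters: int = 20
    k: int = 0
    residuals: list = field(default_factory=list)  # per-iteration (r1, r2)
    converged: bool = False


@dataclass(frozen=True)
class FsiParams:
    """Numerical knobs of the coupled step."""

    eta: float = 1e-4              # penalization time scale, s
    cfl_limit: float = 0.7
    max_substeps: int = 16
    torque_samples: int = 40
    divergence_factor: float = 1e3


def relaxed_update(theta_ddot_k: float, M_k: float, I: float, omega: float) -> float:
    """Under-relaxed Gauss-Seidel update of the angular acceleration."""
    if not (0.0 < omega <= 1.0):
        raise ValueError("omega must lie in (0, 1]")
    if I <= 0:
        raise ValueError("moment of inertia must be positive")
    return theta_ddot_k + omega * (M_k / I - theta_ddot_k)


def aitken_omega(
    residual_k: float,
    residual_km1: float,
    omega_prev: float,
    omega_min: float = 0.05,
    omega_max: float = 1.0,
) -> float:
    """Scalar Aitken delta-squared update of the relaxation factor.

    A near-zero residual difference keeps the previous factor (guard path).
    """
    denom = residual_k - residual_km1
    scale = max(abs(residual_k), abs(residual_km1), 1e-300)
    if abs(denom) < 1e-12 * scale:
        return omega_prev
    omega_new = -omega_prev * residual_km1 / denom
    return float(np.clip(omega_new, omega_min, omega_max))


def _advance_flow(flow0, masks, dt, params: FsiParams):
    """Advance the flow over dt, halving the internal step on CFL violations."""
    n_sub = 1
    speed = flow0.max_speed()
    if speed > 0:
        n_sub = max(1, int(np.ceil(speed * dt / (0.9 * params.cfl_limit * flow0.grid.h))))
    n_sub = min(n_sub, params.max_substeps)
    while True:
        try:
            f = flow0
            for _ in range(n_sub):
                f = step(f, masks, dt / n_sub, eta=params.eta, cfl_limit=params.cfl_limit)
            return f, n_sub
        except RuntimeError:
            if n_sub >= params.max_substeps:
                raise
            n_sub = min(2 * n_sub, params.max_substeps)


def _tentative(leaflet: LeafletState, theta_ddot: float, dt: float) -> LeafletState:
    new = leaflet.copy()
    new.theta_ddot = theta_ddot
    new.theta_dot = leaflet.theta_dot + dt * theta_ddot
    new.theta = leaflet.theta + np.rad2deg(dt * 0.5 * (leaflet.theta_dot + new.theta_dot))
    if new.theta >= new.theta_max:
        new.theta = new.theta_max
        if new.theta_dot > 0:
            new.theta_dot = 0.0
    elif new.theta <= new.theta_min:
        new.theta = new.theta_min
        if new.theta_dot < 0:
            new.theta_dot = 0.0
    return new


def _pinned(lf: LeafletState, M: float) -> bool:
    """Constraint active: resting on a stop with the torque pressing into it."""
    eps = 1e-12
    if lf.theta >= lf.theta_max - eps and M >= 0 and lf.theta_dot <= 0:
        return True
    if lf.theta <= lf.theta_min + eps and M <= 0 and lf.theta_dot >= 0:
        return True
    return False


def fsi_timestep(
    flow: FlowField,
    leaflets: list[LeafletState],
    coupling: CouplingState,
    dt: float,
    wall_raster: WallRaster,
    params: FsiParams = FsiParams(),
    torque_fn=None,
    advance_flow: bool = True,
):
    """One coupled time step; returns (flow, leaflets, coupling) at t + dt.

    The flow is re-advanced from the committed state in every coupling
    iteration; the pressure matrix (walls only) is factorized once per step
    and shared, since the leaflets are penalized inside the projection domain.
    On non-convergence at ``max_iters`` the last iterate is committed with a
    warning; residual growth beyond ``divergence_factor`` aborts.
    """
    if torque_fn is None:
        torque_fn = lambda fld, lf, msk: compute_torque(
            fld, lf, msk, n_samples=params.torque_samples
        )
    grid = flow.grid
    theta_ddot = np.array([lf.theta_ddot for lf in leaflets], dtype=float)
    inertia = np.array([lf.I_moment for lf in leaflets], dtype=float)

    r_prev = [None] * len(leaflets)
    r_first = None
    cpl = CouplingState(
        omega=coupling.omega.copy(),
        omega_min=coupling.omega_min,
        omega_max=coupling.omega_max,
        tol_rel=coupling.tol_rel,
        max_iters=coupling.max_iters,
    )
    flow_k = flow
    masks = SolidMasks(wall=wall_raster)
    tent = list(leaflets)

    for k in range(1, cpl.max_iters + 1):
        cpl.k = k
        tent = [_tentative(lf, a, dt) for lf, a in zip(leaflets, theta_ddot)]
        if advance_flow:
            masks = SolidMasks(wall=wall_raster, leaflets=rasterize_leaflets(grid, tent))
            flow_k, _ = _advance_flow(flow, masks, dt, params)
        M = np.array([torque_fn(flow_k, lf, masks) for lf in tent])
        if not np.all(np.isfinite(M)):
            raise RuntimeError("non-finite leaflet torque")

        resid = M / inertia - theta_ddot
        for i, lf in enumerate(tent):
            if _pinned(lf, M[i]):
                theta_ddot[i] = 0.0
                resid[i] = 0.0
        cpl.residuals.append(tuple(np.abs(resid)))

        rmax = float(np.abs(resid).max())
        if r_first is None:
            r_first = max(rmax, 1.0)
        elif rmax > params.divergence_factor * r_first:
            raise RuntimeError(
                f"FSI iteration diverging: residual {rmax:.3g} rad/s^2 "
                f"(initial {r_first:.3g})"
            )
        scale = max(1.0, float(np.abs(theta_ddot).max()))
        if rmax < cpl.tol_rel * scale:
            cpl.converged = True
            break

        for i in range(len(leaflets)):
            if r_prev[i] is not None:
                cpl.omega[i] = aitken_omega(
                    resid[i], r_prev[i], cpl.omega[i], cpl.omega_min, cpl.omega_max
                )
            theta_ddot[i] = relaxed_update(theta_ddot[i], M[i], inertia[i], cpl.omega[i])
            r_prev[i] = resid[i]

    if not cpl.converged:
        warnings.warn(
            f"FSI step at t={flow.t:.4f}s not converged after {cpl.max_iters} "
            f"iterations (residual {rmax:.3g} rad/s^2); committing last iterate",
            RuntimeWarning,
        )

    committed = []
    for lf, a, m in zip(leaflets, theta_ddot, M):
        new = lf.copy()
        new.M = float(m)
        new.theta_ddot = float(a)
        new.theta_dot = lf.theta_dot + dt * a
        new.theta = lf.theta + np.rad2deg(dt * 0.5 * (lf.theta_dot + new.theta_dot))
        committed.append(enforce_travel_limits(new))
    return flow_k, committed, cpl


# ---------------------------------------------------------------------------
# Run orchestration
# ---------------------------------------------------------------------------

def _scale_poly_to_m(poly):
    return shapely.transform(poly, lambda a: a * 1e-3)


def run_diastole(config=None, progress: bool = False) -> DiagnosticSeries:
    """Full-diastole FSI run from a (possibly empty) configuration document.

    Orchestrates waveform -> wall kinematics -> coupled time loop, and
    collects leaflet traces, the inlet-to-apex pressure difference, anterior
    circulation and field snapshots at the configured T* list.  The run is
    deterministic for a fixed configuration.
    """
    cfg: SimulationConfig = validate_config(config)
    geom = cfg.geometry.build()
    schedule = cfg.waveform.build()
    grid = cfg.fluid.build_grid()
    leaflets = cfg.leaflet.build(geom)
    params = FsiParams(
        eta=cfg.fluid.penalization_eta_s,
        cfl_limit=cfg.fluid.cfl_limit,
        max_substeps=cfg.fluid.max_substeps,
        torque_samples=cfg.coupling.torque_samples,
        divergence_factor=cfg.coupling.divergence_factor,
    )
    dt = cfg.fluid.dt_ms * 1e-3
    T = schedule.period_T

    from .geometry import total_cavity_volume, truncated_spheroid_volume

    sv = truncated_spheroid_volume(geom.c_max, geom) - truncated_spheroid_volume(
        geom.c_min, geom
    )
    wave = build_inflow(schedule, sv, geom.d_inlet, dt)
    traj = axis_trajectory(wave, geom)

    end_tstar = cfg.output.end_tstar if cfg.output.end_tstar is not None else schedule.a_end
    n_steps = int(round(end_tstar * T / dt))
    n_steps = min(n_steps, len(traj.t) - 1)

    # static domain helpers --------------------------------------------------
    x_lo, x_hi = (v * 1e-3 for v in geom.mitral_x_range)
    y_top = geom.mitral_top_y * 1e-3
    inlet_line_y = y_top - 2.5 * grid.h
    inlet_fn = lambda X, Y: (Y > inlet_line_y) & (X > x_lo) & (X < x_hi)
    root_m = np.asarray(geom.outlet_root) * 1e-3
    d_out = geom.outlet_direction
    s_cut = (geom.outlet_tube_length * 1e-3) - 3.5 * grid.h
    outlet_fn = lambda X, Y: ((X - root_m[0]) * d_out[0] + (Y - root_m[1]) * d_out[1]) > s_cut
    inlet_dir = np.array([0.0, -1.0])

    probe_inlet = np.array([geom.mitral_center_x * 1e-3, inlet_line_y - 2.0 * grid.h])

    snap_steps = {
        int(round(ts * T / dt)): ts for ts in cfg.output.snapshot_t_stars
        if ts * T / dt <= n_steps + 0.5
    }

    flow = FlowField.quiescent(grid, rho=cfg.fluid.rho_kg_m3, mu=cfg.fluid.mu_pa_s)
    coupling = CouplingState(
        omega=np.array([cfg.coupling.omega_init] * 2),
        omega_min=cfg.coupling.omega_min,
        omega_max=cfg.coupling.omega_max,
        tol_rel=cfg.coupling.tol_rel,
        max_iters=cfg.coupling.max_iters,
    )

    rec = {
        "t": [], "dp": [], "circ": [], "theta": {lf.label: [] for lf in leaflets},
        "omega": {lf.label: [] for lf in leaflets}, "c": [], "vol": [], "vin": [],
        "iters": [], "cfl": [], "mass": [],
    }
    snapshots = {}
    impacts = {lf.label: [] for lf in leaflets}
    area_prev = None
    t_area_prev = None
    div_max = 0.0

    for n in range(n_steps):
        t1 = (n + 1) * dt
        c1 = float(traj.c_mm[n + 1])
        cdot1 = float(traj.c_dot_mm_s[n + 1])
        v_in = float(wave.velocity(t1))

        section = midplane_section(c1, geom, resolution=cfg.geometry.resolution_mm)
        cavity_m = _scale_poly_to_m(section.cavity)
        pts_mm, vel_mm = wall_kinematics(c1, cdot1, geom)
        wall_raster = fl.rasterize_wall(
            grid, cavity_m, inlet_fn, outlet_fn, inlet_dir, inlet_speed=v_in,
            wall_pts=pts_mm * 1e-3, wall_vel=vel_mm * 1e-3,
        )

        try:
            flow, leaflets, coupling = fsi_timestep(
                flow, leaflets, coupling, dt, wall_raster, params
            )
        except Exception as exc:
            raise RuntimeError(f"run failed at T*={t1 / T:.4f}: {exc}") from exc

        masks = SolidMasks(
            wall=wall_raster, leaflets=rasterize_leaflets(grid, leaflets)
        )
        for lf in leaflets:
            impacts[lf.label] = list(lf.impacts)

        if (n + 1) % cfg.output.trace_stride == 0 or (n + 1) in snap_steps:
            s1 = float(_s_term(c1, geom))
            apex_y = -c1 * (1.0 + s1) * 1e-3
            probe_apex = np.array([0.0, apex_y + 2e-3])
            dp = pressure_difference(flow, (probe_inlet, probe_apex), masks)
            region = (grid.x0, 0.0, apex_y / 2.0, 0.0)
            circ = anterior_circulation(flow, region, masks)
            area = cavity_m.area
            fluxes = fl.boundary_fluxes(flow, wall_raster)
            mass_res = np.nan
            if area_prev is not None:
                mass_res = fluxes["wall_out"] - (area - area_prev) / (t1 - t_area_prev)
            area_prev = area
            t_area_prev = t1
            div_max = max(div_max, fl.max_divergence(flow, masks))

            rec["t"].append(t1)
            rec["dp"].append(dp)
            rec["circ"].append(circ)
            for lf in leaflets:
                rec["theta"][lf.label].append(lf.theta)
                rec["omega"][lf.label].append(lf.theta_dot)
            rec["c"].append(c1)
            rec["vol"].append(total_cavity_volume(c1, geom))
            rec["vin"].append(v_in)
            rec["iters"].append(coupling.k)
            rec["cfl"].append(flow.max_speed() * dt / grid.h)
            rec["mass"].append(mass_res)

        if (n + 1) in snap_steps:
            snapshots[snap_steps[n + 1]] = snapshot_fields(flow, masks)

        if progress and (n + 1) % 50 == 0:
            print(
                f"  step {n + 1}/{n_steps}  T*={t1 / T:.3f}  "
                f"theta=({leaflets[0].theta:.1f},{leaflets[1].theta:.1f}) deg  "
                f"iters={coupling.k}",
                flush=True,
            )

    t_arr = np.asarray(rec["t"])
    series = DiagnosticSeries(
        t_star=t_arr / T,
        t_s=t_arr,
        delta_p=np.asarray(rec["dp"]),
        theta={k: np.asarray(v) for k, v in rec["theta"].items()},
        omega={k: np.asarray(v) for k, v in rec["omega"].items()},
        circulation_anterior=np.asarray(rec["circ"]),
        c_mm=np.asarray(rec["c"]),
        volume_ml=np.asarray(rec["vol"]),
        v_inlet=np.asarray(rec["vin"]),
        snapshots=snapshots,
        impacts=impacts,
        fsi_iterations=np.asarray(rec["iters"], int),
        cfl_history=np.asarray(rec["cfl"]),
        mass_residual=np.asarray(rec["mass"]),
        meta={
            "grid": grid,
            "dt_s": dt,
            "period_s": T,
            "n_steps": n_steps,
            "config": emit_config(cfg),
            "config_hash": config_hash(cfg),
            "max_divergence": div_max,
        },
    )
    return series
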