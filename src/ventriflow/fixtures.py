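"""Miniature benchmark fixtures: seconds-scale configurations with known answers.

Three fixtures are exposed:

``channel_benchmark``
    Pressure-driven development of plane channel flow at low Reynolds number;
    the steady profile must be parabolic with a centreline-to-mean velocity
    ratio of 1.5 (Poiseuille).

``scripted_torque``
    A single leaflet under constant torque from rest; the trace must match
    the closed-form theta(t) = theta0 + M t^2 / (2 I).

``coarse_diastole``
    A coarse-grid, full-diastole FSI configuration that runs in about a
    minute and must keep both leaflets within their travel limits while
    reaching full opening during the E-wave.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from shapely.geometry import Polygon

from . import fluid as fl
from .fluid import FlowField, Grid, SolidMasks
from .leaflets import LeafletState, advance_angle

FIXTURE_NAMES = ("channel_benchmark", "scripted_torque", "coarse_diastole")

__all__ = ["make_fixture", "run_channel", "scripted_torque_trace", "FIXTURE_NAMES"]


@dataclass
class ChannelResult:
    """Steady-state channel profile and the quantities the benchmark checks."""

    grid: Grid
    flow: FlowField
    masks: SolidMasks
    y: np.ndarray            # profile sample heights (m)
    profile: np.ndarray      # streamwise velocity (m/s)
    max_over_mean: float
    u_mean: float
    width: float
    mu: float


def channel_masks(
    grid: Grid, length: float, width: float, inlet_speed: float
) -> SolidMasks:
    """Rectangular channel [0,length]x[0,width] with a velocity cap at the left
    end and a pressure outlet at the right end."""
    cavity = Polygon(
        [(0.0, 0.0), (length, 0.0), (length, width), (0.0, width)]
    )
    inlet_fn = lambda X, Y: X < 2.5 * grid.h
    outlet_fn = lambda X, Y: X > length - 2.5 * grid.h
    wall = fl.rasterize_wall(
        grid, cavity, inlet_fn, outlet_fn, inlet_dir=np.array([1.0, 0.0]),
        inlet_speed=inlet_speed,
    )
    return SolidMasks(wall=wall)


def run_channel(
    n_across: int = 12,
    width: float = 0.010,
    length: float = 0.060,
    u_in: float = 0.02,
    mu: float = 0.105,
    rho: float = 1050.0,
    t_end: float = 0.6,
    dt: float | None = None,
    sample_frac: float = 0.8,
) -> ChannelResult:
    """Step the channel to steady state and extract the developed profile.

    The default viscosity gives Re ~ 2, so the flow develops within a couple
    of diameters and reaches steady state in a fraction of a second.
    """
    h = width / n_across
    nx = int(round(length / h)) + 2
    ny = n_across + 2
    grid = Grid(nx=nx, ny=ny, h=h, x0=-h, y0=-h)
    masks = channel_masks(grid, length, width, u_in)
    flow = FlowField.quiescent(grid, rho=rho, mu=mu)
    if dt is None:
        dt = 0.2 * h**2 / (mu / rho)
    n_steps = int(np.ceil(t_end / dt))
    for _ in range(n_steps):
        flow = step_channel(flow, masks, dt)
    i = int(round((sample_frac * length + h) / h))
    col = flow.u[i, :]
    mask = masks.wall.unknown_u[i, :]
    prof = col[mask]
    y = grid.yc[mask]
    # centreline and bulk velocity from the fitted parabola (the profile is
    # sampled at cell centres, so the raw max misses the vertex by O(h^2))
    coef = np.polyfit(y, prof, 2)
    y_vertex = -coef[1] / (2.0 * coef[0])
    u_center = float(np.polyval(coef, y_vertex))
    roots = np.sort(np.roots(coef))
    w_fit = float(roots[1] - roots[0])
    u_mean = float(
        np.polyval(np.polyint(coef), roots[1]) - np.polyval(np.polyint(coef), roots[0])
    ) / w_fit
    return ChannelResult(
        grid=grid, flow=flow, masks=masks, y=y, profile=prof,
        max_over_mean=u_center / u_mean,
        u_mean=u_mean, width=w_fit, mu=mu,
    )


def step_channel(flow: FlowField, masks: SolidMasks, dt: float) -> FlowField:
    return fl.step(flow, masks, dt)


def scripted_torque_trace(
    M: float = 2e-4,
    dt: float = 1e-4,
    n_steps: int = 100,
    theta0: float = 30.0,
    theta_max: float = 361.0,
):
    """Integrate a leaflet under constant torque and return (t, theta_deg)
    together with the closed-form solution."""
    lf = LeafletState(
        label="anterior", pivot=(0.0, 0.0), hand=+1, theta=theta0,
        theta_min=0.0, theta_max=theta_max,
    )
    t = np.arange(n_steps + 1) * dt
    theta = [lf.theta]
    for _ in range(n_steps):
        lf = advance_angle(lf, M, dt)
        theta.append(lf.theta)
    closed = theta0 + np.rad2deg(M * t**2 / (2.0 * lf.I_moment))
    return t, np.asarray(theta), closed


def make_fixture(name: str) -> dict:
    """Return a miniature configuration plus its expected outputs."""
    if name == "channel_benchmark":
        return {
            "config": {
                "n_across": 12, "width": 0.010, "length": 0.060,
                "u_in": 0.02, "mu": 0.105, "rho": 1050.0, "t_end": 0.6,
            },
            "expected": {"max_over_mean": 1.5, "rtol": 0.05},
            "run": lambda cfg: run_channel(**cfg),
        }
    if name == "scripted_torque":
        cfg = {"M": 2e-4, "dt": 1e-4, "n_steps": 100, "theta0": 30.0}
        return {
            "config": cfg,
            "expected": {"closed_form": "theta0 + M t^2 / (2 I)", "rtol": 0.005},
            "run": lambda c: scripted_torque_trace(**c),
        }
    if name == "coarse_diastole":
        return {
            "config": {
                "fluid": {"nx": 48, "ny": 84, "h_mm": 1.875, "dt_ms": 1.936},
                "geometry": {"resolution_mm": 1.5},
                "output": {"trace_stride": 2, "snapshot_t_stars": [0.25]},
            },
            "expected": {"theta_max_deg": 85.0, "theta_min_deg": 25.0},
            "run": None,  # run with coupling.run_diastole
        }
    raise ValueError(f"unknown fixture {name!r}; choose from {FIXTURE_NAMES}")
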