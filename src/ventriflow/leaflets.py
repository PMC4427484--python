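"""Rigid-body rotation of the two valve leaflets.

Each leaflet is an idealized flat plate (chord 9.5 mm, thickness 0.8 mm for a
25 mm valve) pivoting about a fixed hinge point in the valve housing.  With
hinge damping neglected the motion is Newton's second law for rotation,
theta_ddot = M / I, where M is the fluid torque about the pivot and I the
moment of inertia per unit depth (pyrolytic-carbon density 2000 kg/m^3).

The opening angle theta is measured from the housing plane: 25 deg is fully
closed, 85 deg fully open, and the travel is enforced by a perfectly
inelastic stop (the "blocking mechanism"): on impact the angle is clamped
and the angular velocity zeroed, with the pre-impact angular velocity
recorded for diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from shapely.geometry import Polygon

from .fluid import FlowField, SolidMasks, fill_solid_pressure

PYROLYTIC_CARBON_DENSITY = 2000.0  # kg/m^3

__all__ = [
    "LeafletState",
    "moment_of_inertia",
    "make_leaflets",
    "compute_torque",
    "advance_angle",
    "enforce_travel_limits",
]


def moment_of_inertia(
    chord_mm: float,
    thickness_mm: float,
    pivot_offset_mm: float,
    density: float = PYROLYTIC_CARBON_DENSITY,
) -> float:
    """Plate moment of inertia about the pivot, kg m^2 per unit depth.

    The pivot sits ``pivot_offset`` from the outer (short-arm) edge; exact
    rectangle formula including the thin transverse term.
    """
    L = chord_mm * 1e-3
    t = thickness_mm * 1e-3
    a_minus = pivot_offset_mm * 1e-3
    a_plus = L - a_minus
    return density * (t * (a_plus**3 + a_minus**3) / 3.0 + t**3 * L / 12.0)


@dataclass
class LeafletState:
    """State of one leaflet; angles in degrees, rates in rad/s."""

    label: str                      # "anterior" | "posterior"
    pivot: tuple[float, float]      # mm
    hand: int                       # +1: long arm toward +x when closed (anterior)
    chord: float = 9.5              # mm
    thickness: float = 0.8          # mm
    pivot_offset: float = 2.5       # mm, pivot to outer edge
    density: float = PYROLYTIC_CARBON_DENSITY
    theta: float = 25.0             # deg
    theta_dot: float = 0.0          # rad/s
    theta_ddot: float = 0.0         # rad/s^2
    M: float = 0.0                  # N m per unit depth
    xi: float = 0.0                 # damping, neglected
    theta_min: float = 25.0
    theta_max: float = 85.0
    restitution: float = 0.0
    I_moment: float | None = None   # kg m^2 per unit depth
    impacts: list = field(default_factory=list)  # (theta_deg, impact rad/s)

    def __post_init__(self) -> None:
        if self.hand not in (+1, -1):
            raise ValueError("hand must be +1 or -1")
        if self.I_moment is None:
            self.I_moment = moment_of_inertia(
                self.chord, self.thickness, self.pivot_offset, self.density
            )
        if self.I_moment <= 0:
            raise ValueError("moment of inertia must be positive")
        # theta may transiently exceed the travel limits between an update and
        # enforce_travel_limits; range validation happens at configuration time

    # -- geometry ----------------------------------------------------------
    @property
    def sense(self) -> int:
        """Sign mapping theta_dot to out-of-plane angular velocity omega_z."""
        return -self.hand

    @property
    def omega_z(self) -> float:
        return self.sense * self.theta_dot

    @property
    def chord_dir(self) -> np.ndarray:
        """Unit vector from pivot toward the long (inner) edge."""
        th = np.deg2rad(self.theta)
        return np.array([self.hand * np.cos(th), -np.sin(th)])

    @property
    def normal(self) -> np.ndarray:
        e = self.chord_dir
        return np.array([-e[1], e[0]])

    @property
    def pivot_m(self) -> np.ndarray:
        return np.asarray(self.pivot, dtype=float) * 1e-3

    @property
    def thickness_m(self) -> float:
        return self.thickness * 1e-3

    def polygon_mm(self, inflate: float = 0.0) -> Polygon:
        """Leaflet rectangle in mm, optionally inflated by ``inflate`` mm."""
        e = self.chord_dir
        n = self.normal
        p = np.asarray(self.pivot, dtype=float)
        a_plus = self.chord - self.pivot_offset + inflate
        a_minus = self.pivot_offset + inflate
        hw = self.thickness / 2.0 + inflate
        c0 = p - a_minus * e - hw * n
        c1 = p + a_plus * e - hw * n
        c2 = p + a_plus * e + hw * n
        c3 = p - a_minus * e + hw * n
        return Polygon([c0, c1, c2, c3])

    def solid_polygon(self, inflate: float = 0.0) -> Polygon:
        """Leaflet rectangle in metres, inflated by ``inflate`` metres (used to
        keep a plate thinner than a grid cell visible to the rasterizer)."""
        poly = self.polygon_mm(inflate=inflate * 1e3)
        return Polygon(np.asarray(poly.exterior.coords) * 1e-3)

    def copy(self) -> "LeafletState":
        new = replace(self)
        new.impacts = list(self.impacts)
        return new


def make_leaflets(
    mitral_center_x: float = 5.5,
    pivot_y: float = 9.0,
    pivot_half_separation: float = 6.5,
    **kwargs,
) -> list[LeafletState]:
    """The anterior/posterior leaflet pair of the bileaflet valve (mm inputs)."""
    ant = LeafletState(
        label="anterior",
        pivot=(mitral_center_x - pivot_half_separation, pivot_y),
        hand=+1,
        **kwargs,
    )
    post = LeafletState(
        label="posterior",
        pivot=(mitral_center_x + pivot_half_separation, pivot_y),
        hand=-1,
        **kwargs,
    )
    return [ant, post]


# ---------------------------------------------------------------------------
# Fluid torque
# ---------------------------------------------------------------------------

def _bilinear(field2d: np.ndarray, grid, pts: np.ndarray) -> np.ndarray:
    """Bilinear sample of a cell-centred field at points (m)."""
    fx = (pts[:, 0] - (grid.x0 + 0.5 * grid.h)) / grid.h
    fy = (pts[:, 1] - (grid.y0 + 0.5 * grid.h)) / grid.h
    i0 = np.clip(np.floor(fx).astype(int), 0, grid.nx - 2)
    j0 = np.clip(np.floor(fy).astype(int), 0, grid.ny - 2)
    tx = np.clip(fx - i0, 0.0, 1.0)
    ty = np.clip(fy - j0, 0.0, 1.0)
    f00 = field2d[i0, j0]
    f10 = field2d[i0 + 1, j0]
    f01 = field2d[i0, j0 + 1]
    f11 = field2d[i0 + 1, j0 + 1]
    return (
        f00 * (1 - tx) * (1 - ty)
        + f10 * tx * (1 - ty)
        + f01 * (1 - tx) * ty
        + f11 * tx * ty
    )


def compute_torque(
    flow: FlowField,
    leaflet: LeafletState,
    masks: SolidMasks | None = None,
    n_samples: int = 40,
    offset: float | None = None,
) -> float:
    """Fluid torque about the pivot, N m per unit depth; positive opens.

    Surface-traction formulation: the pressure is sampled bilinearly on both
    faces of the plate at probe points offset just outside the rasterized
    solid, and the pressure-jump moment is integrated along the chord.  (In
    the penalization limit this equals the momentum-exchange integral over
    the leaflet's solid cells.)  Viscous skin friction contributes no moment
    to leading order for a thin plate and is neglected.
    """
    grid = flow.grid
    if masks is not None and masks.leaflets is not None:
        # under-resolution guard
        covered = masks.leaflets.cells
        poly = leaflet.solid_polygon(inflate=max(0.0, grid.h - leaflet.thickness_m / 2.0))
        bx = poly.bounds
        X, Y = grid.cell_centers()
        in_box = (X >= bx[0]) & (X <= bx[2]) & (Y >= bx[1]) & (Y <= bx[3])
        if not (covered & in_box).any():
            raise RuntimeError(
                f"leaflet '{leaflet.label}' covers no solid cells at h={grid.h:.3g} m; "
                "refine the grid or inflate the leaflet"
            )

    half_w = max(leaflet.thickness_m / 2.0, grid.h)
    d = offset if offset is not None else half_w + grid.h

    fluid = masks.fluid_cells if masks is not None else np.ones_like(flow.p, bool)
    pf = fill_solid_pressure(flow.p, fluid)

    a_plus = (leaflet.chord - leaflet.pivot_offset) * 1e-3
    a_minus = leaflet.pivot_offset * 1e-3
    s_edges = np.linspace(-a_minus, a_plus, n_samples + 1)
    s_mid = 0.5 * (s_edges[:-1] + s_edges[1:])
    ds = np.diff(s_edges)
    e = leaflet.chord_dir
    n = leaflet.normal
    pts = leaflet.pivot_m[None, :] + s_mid[:, None] * e[None, :]
    p_plus = _bilinear(pf, grid, pts + d * n)
    p_minus = _bilinear(pf, grid, pts - d * n)
    torque_z = float(np.sum(s_mid * (p_minus - p_plus) * ds))
    return leaflet.sense * torque_z


# ---------------------------------------------------------------------------
# Integration and travel limits
# ---------------------------------------------------------------------------

def advance_angle(state: LeafletState, M: float, dt: float) -> LeafletState:
    """Integrate theta_ddot = M/I over dt (damping xi = 0).

    Velocity-Verlet-style update (new velocity first, position from the
    velocity average), exact for piecewise-constant torque; travel limits are
    enforced afterwards.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if not np.isfinite(M):
        raise RuntimeError("non-finite torque")
    new = state.copy()
    new.M = M
    new.theta_ddot = M / state.I_moment
    new.theta_dot = state.theta_dot + dt * new.theta_ddot
    new.theta = state.theta + np.rad2deg(dt * 0.5 * (state.theta_dot + new.theta_dot))
    return enforce_travel_limits(new)


def enforce_travel_limits(state: LeafletState) -> LeafletState:
    """Clamp theta to [theta_min, theta_max]; inelastic stop at the limits."""
    new = state.copy()
    if new.theta > new.theta_max:
        new.theta = new.theta_max
        if new.theta_dot > 0:
            new.impacts.append((new.theta_max, new.theta_dot))
            new.theta_dot = -new.restitution * new.theta_dot
    elif new.theta < new.theta_min:
        new.theta = new.theta_min
        if new.theta_dot < 0:
            new.impacts.append((new.theta_min, -new.theta_dot))
            new.theta_dot = -new.restitution * new.theta_dot
    return new
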