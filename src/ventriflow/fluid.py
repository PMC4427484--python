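"""2-D incompressible flow on the mid-plane with moving rigid boundaries.

Staggered (MAC) Cartesian grid, first-order explicit time stepping with
upwind-biased advection and centred diffusion, and a pressure projection to
the discrete divergence-free space (direct sparse factorization, so discrete
continuity holds to round-off in every fluid cell).

Moving boundaries come in two flavours:

* the ventricular wall, housing and tube walls are *excluded* cells whose
  interface faces carry the prescribed boundary velocity (stair-step ghost
  faces) — this makes the discrete mass bookkeeping of the expanding cavity
  exact;
* the valve leaflets are Brinkman-penalized inside the projection domain: a
  strong volumetric drag relaxes the fluid velocity toward the local
  rigid-body velocity over the penalization time scale ``eta``.  This keeps
  the pressure matrix independent of leaflet position, so one factorization
  serves all coupling iterations of a time step.

The atrial inlet is a capped tube end whose cap cells carry the inflow
velocity; the aortic outlet is a strip of fixed-gauge-pressure cells that
absorbs whatever net flux the 2-D area balance requires, mirroring a
constant-static-pressure outlet.  Blood is Newtonian with density
1050 kg/m^3 and dynamic viscosity 3.5 mPa s by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np
import shapely
from scipy import sparse
from scipy.sparse.linalg import splu
from scipy.spatial import cKDTree

FLUID, WALL, INLET, OUTLET = 0, 1, 2, 3

RHO_BLOOD = 1050.0     # kg/m^3
MU_BLOOD = 3.5e-3      # Pa s

__all__ = [
    "Grid",
    "FlowField",
    "WallRaster",
    "LeafletRaster",
    "SolidMasks",
    "rasterize_wall",
    "rasterize_leaflets",
    "rasterize_solids",
    "apply_inlet_outlet",
    "step",
    "divergence",
    "kinetic_energy",
    "fill_solid_pressure",
    "FLUID",
    "WALL",
    "INLET",
    "OUTLET",
]


@dataclass(frozen=True)
class Grid:
    """Uniform square-cell staggered grid over [x0, x0+nx*h] x [y0, y0+ny*h] (m)."""

    nx: int
    ny: int
    h: float
    x0: float
    y0: float

    @property
    def xc(self) -> np.ndarray:
        return self.x0 + (np.arange(self.nx) + 0.5) * self.h

    @property
    def yc(self) -> np.ndarray:
        return self.y0 + (np.arange(self.ny) + 0.5) * self.h

    @property
    def xu(self) -> np.ndarray:
        return self.x0 + np.arange(self.nx + 1) * self.h

    @property
    def yv(self) -> np.ndarray:
        return self.y0 + np.arange(self.ny + 1) * self.h

    def cell_centers(self):
        return np.meshgrid(self.xc, self.yc, indexing="ij")

    def u_faces(self):
        return np.meshgrid(self.xu, self.yc, indexing="ij")

    def v_faces(self):
        return np.meshgrid(self.xc, self.yv, indexing="ij")


@dataclass
class FlowField:
    """Velocity/pressure state on a staggered grid (SI units)."""

    grid: Grid
    u: np.ndarray            # (nx+1, ny)
    v: np.ndarray            # (nx, ny+1)
    p: np.ndarray            # (nx, ny), gauge
    rho: float = RHO_BLOOD
    mu: float = MU_BLOOD
    t: float = 0.0

    @classmethod
    def quiescent(cls, grid: Grid, rho: float = RHO_BLOOD, mu: float = MU_BLOOD) -> "FlowField":
        return cls(
            grid=grid,
            u=np.zeros((grid.nx + 1, grid.ny)),
            v=np.zeros((grid.nx, grid.ny + 1)),
            p=np.zeros((grid.nx, grid.ny)),
            rho=rho,
            mu=mu,
        )

    @property
    def nu(self) -> float:
        return self.mu / self.rho

    def copy(self) -> "FlowField":
        return FlowField(
            grid=self.grid, u=self.u.copy(), v=self.v.copy(), p=self.p.copy(),
            rho=self.rho, mu=self.mu, t=self.t,
        )

    def max_speed(self) -> float:
        return max(float(np.abs(self.u).max()), float(np.abs(self.v).max()))


# ---------------------------------------------------------------------------
# Rasterization
# ---------------------------------------------------------------------------

@dataclass
class WallRaster:
    """Cell classification and prescribed face velocities for one wall state."""

    grid: Grid
    cell_type: np.ndarray          # (nx, ny) int
    us_u: np.ndarray               # prescribed u at faces (valid on ~unknown_u)
    us_v: np.ndarray
    unknown_u: np.ndarray          # bool masks of projected (free) faces
    unknown_v: np.ndarray
    inlet_u: np.ndarray            # bool masks of inlet-cap faces
    inlet_v: np.ndarray
    inlet_dir: np.ndarray          # unit inflow direction
    outlet_gauge: float = 0.0      # Dirichlet pressure at outlet cells, Pa

    @property
    def fluid(self) -> np.ndarray:
        return self.cell_type == FLUID


@dataclass
class LeafletRaster:
    """Penalization masks and rigid-body velocities of the leaflets."""

    chi_u: np.ndarray              # bool (nx+1, ny)
    chi_v: np.ndarray              # bool (nx, ny+1)
    sol_u: np.ndarray
    sol_v: np.ndarray
    cells: np.ndarray              # bool (nx, ny) cell-centre containment
    per_leaflet_cells: list        # list of bool (nx, ny)


@dataclass
class SolidMasks:
    """Combined solid description handed to the flow step.

    Owns the factorized pressure operator: the projection uses a
    permeability-weighted Laplacian whose face coefficient is 1 in open fluid
    and 1/(1 + dt/eta) inside penalized leaflets, so that in the limit of a
    vanishing penalization time the plates become impermeable to the
    correction as well as to the prediction.
    """

    wall: WallRaster
    leaflets: LeafletRaster | None = None
    _lu: object = field(default=None, repr=False)
    _pidx: np.ndarray = field(default=None, repr=False)
    _n_outlet_nb: np.ndarray = field(default=None, repr=False)
    _coeff_key: tuple = field(default=None, repr=False)
    _au: np.ndarray = field(default=None, repr=False)
    _av: np.ndarray = field(default=None, repr=False)

    @property
    def grid(self) -> Grid:
        return self.wall.grid

    @property
    def solid_cells(self) -> np.ndarray:
        s = self.wall.cell_type != FLUID
        if self.leaflets is not None:
            s = s | self.leaflets.cells
        return s

    @property
    def fluid_cells(self) -> np.ndarray:
        f = self.wall.cell_type == FLUID
        if self.leaflets is not None:
            f = f & ~self.leaflets.cells
        return f

    def face_coeffs(self, dt: float, eta: float):
        """Projection face coefficients for the current penalization factor."""
        g = self.grid
        au = np.ones((g.nx + 1, g.ny))
        av = np.ones((g.nx, g.ny + 1))
        if self.leaflets is not None:
            a = 1.0 / (1.0 + dt / eta)
            au[self.leaflets.chi_u] = a
            av[self.leaflets.chi_v] = a
        return au, av

    def lu(self, dt: float, eta: float):
        key = (float(dt), float(eta))
        if self._lu is None or self._coeff_key != key:
            self._au, self._av = self.face_coeffs(dt, eta)
            A, self._pidx, self._n_outlet_nb = _poisson_matrix(
                self.wall.cell_type, self._au, self._av
            )
            self._lu = splu(A.tocsc())
            self._coeff_key = key
        return self._lu


def _face_types(cell_type: np.ndarray):
    """Unknown-face masks from cell classification (exterior padded as WALL)."""
    ctp = np.pad(cell_type, 1, constant_values=WALL)
    free = (ctp == FLUID) | (ctp == OUTLET)
    # u-face i (0..nx) between cells i-1 and i at row j
    unknown_u = free[:-1, 1:-1] & free[1:, 1:-1]
    unknown_v = free[1:-1, :-1] & free[1:-1, 1:]
    return unknown_u, unknown_v


def rasterize_wall(
    grid: Grid,
    cavity_poly,
    inlet_fn: Callable[[np.ndarray, np.ndarray], np.ndarray],
    outlet_fn: Callable[[np.ndarray, np.ndarray], np.ndarray] | None,
    inlet_dir: np.ndarray,
    inlet_speed: float = 0.0,
    wall_pts: np.ndarray | None = None,
    wall_vel: np.ndarray | None = None,
    moving_band: float | None = None,
) -> WallRaster:
    """Classify cells as fluid/wall/inlet/outlet and set prescribed face velocities.

    ``cavity_poly`` is a shapely polygon in metres; cells are classified by
    containment of their centres.  ``inlet_fn``/``outlet_fn`` mark sub-regions
    of the cavity (the capped inflow strip and the pressure-outlet strip).
    ``wall_pts``/``wall_vel`` give the moving-boundary polyline and its
    velocities (m, m/s); interface faces within ``moving_band`` of the
    polyline carry the nearest boundary velocity.
    """
    X, Y = grid.cell_centers()
    inside = shapely.contains_xy(cavity_poly, X.ravel(), Y.ravel()).reshape(X.shape)
    ct = np.full((grid.nx, grid.ny), WALL, dtype=np.int8)
    ct[inside] = FLUID
    if inlet_fn is not None:
        ct[inside & inlet_fn(X, Y)] = INLET
    if outlet_fn is not None:
        ct[inside & outlet_fn(X, Y)] = OUTLET
    if not (ct == OUTLET).any():
        raise ValueError("no outlet cells: the pressure problem would be singular")

    # rasterization slivers: drop fluid pockets not connected to the outlet,
    # they would make the pressure problem singular
    from scipy import ndimage

    lab, nlab = ndimage.label((ct == FLUID) | (ct == OUTLET))
    keep = np.unique(lab[ct == OUTLET])
    pocket = (lab > 0) & ~np.isin(lab, keep)
    ct[pocket] = WALL

    unknown_u, unknown_v = _face_types(ct)
    us_u = np.zeros((grid.nx + 1, grid.ny))
    us_v = np.zeros((grid.nx, grid.ny + 1))

    # inlet cap faces: any face touching an INLET cell
    ctp = np.pad(ct, 1, constant_values=WALL)
    inl = ctp == INLET
    inlet_u = (inl[:-1, 1:-1] | inl[1:, 1:-1]) & ~unknown_u
    inlet_v = (inl[1:-1, :-1] | inl[1:-1, 1:]) & ~unknown_v

    raster = WallRaster(
        grid=grid, cell_type=ct, us_u=us_u, us_v=us_v,
        unknown_u=unknown_u, unknown_v=unknown_v,
        inlet_u=inlet_u, inlet_v=inlet_v, inlet_dir=np.asarray(inlet_dir, float),
    )

    # moving-wall faces: prescribed faces near the boundary polyline
    if wall_pts is not None and len(wall_pts):
        band = moving_band if moving_band is not None else 3.0 * grid.h
        tree = cKDTree(wall_pts)
        for arr, mask_unknown, inlet_mask, comp, (FX, FY) in (
            (us_u, unknown_u, inlet_u, 0, grid.u_faces()),
            (us_v, unknown_v, inlet_v, 1, grid.v_faces()),
        ):
            cand = ~mask_unknown & ~inlet_mask & (FY < 2.0 * grid.h)
            if not cand.any():
                continue
            pts = np.column_stack([FX[cand], FY[cand]])
            dist, j = tree.query(pts)
            vals = np.where(dist <= band, wall_vel[j, comp], 0.0)
            arr[cand] = vals

    apply_inlet_outlet(raster, inlet_speed)
    return raster


def apply_inlet_outlet(raster: WallRaster, inlet_speed: float) -> WallRaster:
    """Set the inlet-cap face velocities to ``inlet_speed`` times the inflow
    direction.  The outlet needs no action: its cells hold a fixed gauge
    pressure (0 internally; any constant offset leaves the velocity field
    unchanged)."""
    raster.us_u[raster.inlet_u] = inlet_speed * raster.inlet_dir[0]
    raster.us_v[raster.inlet_v] = inlet_speed * raster.inlet_dir[1]
    return raster


def rasterize_leaflets(grid: Grid, leaflets) -> LeafletRaster:
    """Penalization masks for rigid leaflets.

    ``leaflets`` is a sequence of objects exposing ``solid_polygon(inflate)``
    (shapely, metres), ``pivot_m``, and ``omega_z`` (rad/s, out-of-plane).
    Each solid face stores the local rigid-body velocity omega x r.
    """
    XU, YU = grid.u_faces()
    XV, YV = grid.v_faces()
    XC, YC = grid.cell_centers()
    chi_u = np.zeros(XU.shape, bool)
    chi_v = np.zeros(XV.shape, bool)
    sol_u = np.zeros(XU.shape)
    sol_v = np.zeros(XV.shape)
    cells = np.zeros(XC.shape, bool)
    per_leaflet = []
    xb = (grid.x0, grid.x0 + grid.nx * grid.h)
    yb = (grid.y0, grid.y0 + grid.ny * grid.h)
    for lf in leaflets:
        poly = lf.solid_polygon(inflate=max(0.0, grid.h - lf.thickness_m / 2.0))
        bx = poly.bounds
        if bx[0] < xb[0] or bx[2] > xb[1] or bx[1] < yb[0] or bx[3] > yb[1]:
            raise ValueError(f"leaflet '{lf.label}' polygon escapes the domain box")
        mu_ = shapely.contains_xy(poly, XU.ravel(), YU.ravel()).reshape(XU.shape)
        mv_ = shapely.contains_xy(poly, XV.ravel(), YV.ravel()).reshape(XV.shape)
        mc_ = shapely.contains_xy(poly, XC.ravel(), YC.ravel()).reshape(XC.shape)
        px, py = lf.pivot_m
        om = lf.omega_z
        sol_u[mu_] = -om * (YU[mu_] - py)
        sol_v[mv_] = om * (XV[mv_] - px)
        chi_u |= mu_
        chi_v |= mv_
        cells |= mc_
        per_leaflet.append(mc_)
    return LeafletRaster(
        chi_u=chi_u, chi_v=chi_v, sol_u=sol_u, sol_v=sol_v,
        cells=cells, per_leaflet_cells=per_leaflet,
    )


def rasterize_solids(grid: Grid, cavity_poly, leaflets=(), **wall_kwargs) -> SolidMasks:
    """Full solid description: wall classification plus leaflet penalization."""
    wall = rasterize_wall(grid, cavity_poly, **wall_kwargs)
    lf = rasterize_leaflets(grid, leaflets) if len(leaflets) else None
    return SolidMasks(wall=wall, leaflets=lf)


# ---------------------------------------------------------------------------
# Pressure projection
# ---------------------------------------------------------------------------

def _poisson_matrix(cell_type: np.ndarray, au: np.ndarray, av: np.ndarray):
    """Permeability-weighted 5-point operator over fluid cells.

    Dirichlet toward OUTLET neighbours, Neumann toward walls (their face
    fluxes are prescribed); ``au``/``av`` are the face coefficients (1 in
    open fluid, the penalization factor inside leaflets)."""
    nx, ny = cell_type.shape
    fluid = cell_type == FLUID
    n = int(fluid.sum())
    idx = -np.ones((nx, ny), dtype=np.int64)
    idx[fluid] = np.arange(n)
    ctp = np.pad(cell_type, 1, constant_values=WALL)
    idxp = np.pad(idx, 1, constant_values=-1)

    rows, cols, vals = [], [], []
    diag = np.zeros(n)
    n_outlet_nb = np.zeros(n)
    I, J = np.where(fluid)
    # (shift, face coefficient at the shared face)
    shifts = [
        ((1, 0), au[I + 1, J]),
        ((-1, 0), au[I, J]),
        ((0, 1), av[I, J + 1]),
        ((0, -1), av[I, J]),
    ]
    for (dx, dy), cf in shifts:
        nb_t = ctp[1 + I + dx, 1 + J + dy]
        nb_i = idxp[1 + I + dx, 1 + J + dy]
        m_fluid = nb_t == FLUID
        m_out = nb_t == OUTLET
        diag += np.where(m_fluid | m_out, cf, 0.0)
        n_outlet_nb += np.where(m_out, cf, 0.0)
        rows.append(idx[I[m_fluid], J[m_fluid]])
        cols.append(nb_i[m_fluid])
        vals.append(-cf[m_fluid])
    rows.append(np.arange(n))
    cols.append(np.arange(n))
    vals.append(diag)
    A = sparse.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n),
    )
    return A, idx, n_outlet_nb


def divergence(u: np.ndarray, v: np.ndarray, h: float) -> np.ndarray:
    return (u[1:, :] - u[:-1, :] + v[:, 1:] - v[:, :-1]) / h


def _project(u, v, masks: SolidMasks, rho: float, dt: float, eta: float):
    grid = masks.grid
    wall = masks.wall
    lu = masks.lu(dt, eta)
    fluid = wall.fluid
    div = divergence(u, v, grid.h)
    # A holds the dimensionless weighted 5-point stencil (= -h^2 * div(a grad));
    # Dirichlet neighbours contribute their gauge value to the RHS
    rhs = -(rho / dt) * div[fluid] * grid.h**2
    if wall.outlet_gauge != 0.0:
        rhs = rhs + masks._n_outlet_nb * wall.outlet_gauge
    phi_vec = lu.solve(rhs)
    p = np.zeros((grid.nx, grid.ny))
    p[fluid] = phi_vec
    p[wall.cell_type == OUTLET] = wall.outlet_gauge
    # coefficient-weighted gradient update on unknown faces
    dpx = masks._au[1:-1, :] * (p[1:, :] - p[:-1, :]) / grid.h
    dpy = masks._av[:, 1:-1] * (p[:, 1:] - p[:, :-1]) / grid.h
    un = u.copy()
    vn = v.copy()
    un[1:-1, :][wall.unknown_u[1:-1, :]] -= (dt / rho) * dpx[wall.unknown_u[1:-1, :]]
    vn[:, 1:-1][wall.unknown_v[:, 1:-1]] -= (dt / rho) * dpy[wall.unknown_v[:, 1:-1]]
    return un, vn, p


# ---------------------------------------------------------------------------
# Time step
# ---------------------------------------------------------------------------

def _advect_diffuse(flow: FlowField, dt: float):
    """Explicit upwind advection + centred diffusion tendencies on interior faces."""
    u, v, h, nu = flow.u, flow.v, flow.grid.h, flow.nu
    un = u.copy()
    vn = v.copy()

    # --- u faces, interior i=1..nx-1, j=1..ny-2
    uc = u[1:-1, 1:-1]
    v_at_u = 0.25 * (
        v[:-1, 1:-2] + v[:-1, 2:-1] + v[1:, 1:-2] + v[1:, 2:-1]
    )
    dudx_b = (u[1:-1, 1:-1] - u[:-2, 1:-1]) / h
    dudx_f = (u[2:, 1:-1] - u[1:-1, 1:-1]) / h
    dudy_b = (u[1:-1, 1:-1] - u[1:-1, :-2]) / h
    dudy_f = (u[1:-1, 2:] - u[1:-1, 1:-1]) / h
    adv_u = uc * np.where(uc > 0, dudx_b, dudx_f) + v_at_u * np.where(
        v_at_u > 0, dudy_b, dudy_f
    )
    lap_u = (
        u[2:, 1:-1] + u[:-2, 1:-1] + u[1:-1, 2:] + u[1:-1, :-2] - 4.0 * u[1:-1, 1:-1]
    ) / h**2
    un[1:-1, 1:-1] = u[1:-1, 1:-1] + dt * (-adv_u + nu * lap_u)

    # --- v faces, interior i=1..nx-2, j=1..ny-1
    vc = v[1:-1, 1:-1]
    u_at_v = 0.25 * (
        u[1:-2, :-1] + u[1:-2, 1:] + u[2:-1, :-1] + u[2:-1, 1:]
    )
    dvdx_b = (v[1:-1, 1:-1] - v[:-2, 1:-1]) / h
    dvdx_f = (v[2:, 1:-1] - v[1:-1, 1:-1]) / h
    dvdy_b = (v[1:-1, 1:-1] - v[1:-1, :-2]) / h
    dvdy_f = (v[1:-1, 2:] - v[1:-1, 1:-1]) / h
    adv_v = u_at_v * np.where(u_at_v > 0, dvdx_b, dvdx_f) + vc * np.where(
        vc > 0, dvdy_b, dvdy_f
    )
    lap_v = (
        v[2:, 1:-1] + v[:-2, 1:-1] + v[1:-1, 2:] + v[1:-1, :-2] - 4.0 * v[1:-1, 1:-1]
    ) / h**2
    vn[1:-1, 1:-1] = v[1:-1, 1:-1] + dt * (-adv_v + nu * lap_v)
    return un, vn


def step(
    flow: FlowField,
    masks: SolidMasks,
    dt: float,
    *,
    eta: float = 1e-4,
    cfl_limit: float = 0.7,
    check_cfl: bool = True,
) -> FlowField:
    """Advance the flow one time step.

    Raises on CFL violation (reporting the admissible dt) and on non-finite
    fields.  After the projection, discrete continuity holds in every fluid
    cell to the direct-solver round-off.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    grid = flow.grid
    speed = flow.max_speed()
    if check_cfl and speed * dt / grid.h > cfl_limit:
        raise RuntimeError(
            f"CFL violation: |v|max*dt/h = {speed * dt / grid.h:.2f} > {cfl_limit}; "
            f"admissible dt = {cfl_limit * grid.h / max(speed, 1e-300):.3e} s"
        )
    if not (np.isfinite(flow.u).all() and np.isfinite(flow.v).all()):
        raise RuntimeError("non-finite velocity field")

    wall = masks.wall
    u, v = _advect_diffuse(flow, dt)

    # Brinkman penalization toward leaflet rigid-body velocities (implicit)
    lf = masks.leaflets
    if lf is not None:
        fac = dt / eta
        u[lf.chi_u] = (u[lf.chi_u] + fac * lf.sol_u[lf.chi_u]) / (1.0 + fac)
        v[lf.chi_v] = (v[lf.chi_v] + fac * lf.sol_v[lf.chi_v]) / (1.0 + fac)

    # prescribed (wall / inlet) faces
    u[~wall.unknown_u] = wall.us_u[~wall.unknown_u]
    v[~wall.unknown_v] = wall.us_v[~wall.unknown_v]

    u, v, p = _project(u, v, masks, flow.rho, dt, eta)
    u[~wall.unknown_u] = wall.us_u[~wall.unknown_u]
    v[~wall.unknown_v] = wall.us_v[~wall.unknown_v]

    return FlowField(grid=grid, u=u, v=v, p=p, rho=flow.rho, mu=flow.mu, t=flow.t + dt)


# ---------------------------------------------------------------------------
# Helpers
# ---------------------------------------------------------------------------

def kinetic_energy(flow: FlowField, masks: SolidMasks | None = None) -> float:
    """Total kinetic energy per unit depth (J/m), over fluid faces if masks given."""
    h2 = flow.grid.h**2
    if masks is None:
        return 0.5 * flow.rho * h2 * (float((flow.u**2).sum()) + float((flow.v**2).sum()))
    uu = flow.u[masks.wall.unknown_u]
    vv = flow.v[masks.wall.unknown_v]
    return 0.5 * flow.rho * h2 * (float((uu**2).sum()) + float((vv**2).sum()))


def fill_solid_pressure(p: np.ndarray, fluid: np.ndarray) -> np.ndarray:
    """Extend the pressure into non-fluid cells by nearest-fluid values, so
    bilinear sampling near boundaries stays well defined."""
    from scipy import ndimage

    if fluid.all():
        return p
    _, (ix, iy) = ndimage.distance_transform_edt(~fluid, return_indices=True)
    return p[ix, iy]


def boundary_fluxes(flow: FlowField, wall: WallRaster) -> dict:
    """2-D volume fluxes (m^2/s) across the fluid region's boundary faces.

    Returns ``inlet_in`` (into the fluid through inlet-cap faces),
    ``wall_out`` (out through wall-interface faces, which for a moving wall
    approximates the area sweep rate dA/dt) and ``outlet_out``.  Discrete
    continuity makes inlet_in = wall_out + outlet_out to solver round-off.
    """
    h = flow.grid.h
    ctp = np.pad(wall.cell_type, 1, constant_values=WALL)
    L, R = ctp[:-1, 1:-1], ctp[1:, 1:-1]        # u-face neighbours (nx+1, ny)
    B, T = ctp[1:-1, :-1], ctp[1:-1, 1:]        # v-face neighbours (nx, ny+1)
    out = {}
    for typ, key in ((INLET, "inlet"), (WALL, "wall"), (OUTLET, "outlet")):
        # outward flux from the fluid side of each interface face
        flux_out = (
            flow.u[(L == FLUID) & (R == typ)].sum()
            - flow.u[(R == FLUID) & (L == typ)].sum()
            + flow.v[(B == FLUID) & (T == typ)].sum()
            - flow.v[(T == FLUID) & (B == typ)].sum()
        ) * h
        out[key] = float(flux_out)
    return {
        "inlet_in": -out["inlet"],
        "wall_out": out["wall"],
        "outlet_out": out["outlet"],
    }


def max_divergence(flow: FlowField, masks: SolidMasks) -> float:
    div = divergence(flow.u, flow.v, flow.grid.h)
    return float(np.abs(div[masks.wall.fluid]).max())
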