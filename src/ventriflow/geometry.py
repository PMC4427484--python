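"""Idealized left-ventricle geometry: truncated prolate spheroid + valve tubes.

The lower portion of the ventricle is a prolate spheroid of long semi-axis
``c`` (mm) and long-to-short-axis ratio ``alpha``, truncated by the plane of
the mitral annulus where the cross-section circle has radius ``r_trunc``.
Its volume has the closed form

    V(c) = (pi c^3 / alpha^2) * [2/3 + s - s^3/3],   s = sqrt(1 - alpha^2 r^2 / c^2)

which is the spheroid volume minus the cap above the truncation plane.

Coordinate convention: x points to the anatomical posterior, y runs from the
apex (negative) to the base (positive).  The truncation (valve) plane is held
fixed at y = 0 and the apex translates as ``c`` changes, so the valve housing
and both tubes are static.  Clockwise rotation in the (x, y) plane (atrium
up, anterior left) corresponds to negative out-of-plane vorticity.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np
import shapely
from scipy.optimize import brentq
from shapely.geometry import Polygon
from shapely.ops import unary_union

ML_PER_MM3 = 1e-3

__all__ = [
    "VentricleGeometry",
    "MidplaneSection",
    "truncated_spheroid_volume",
    "total_cavity_volume",
    "calibrate_upper_volume",
    "invert_volume_to_axis",
    "midplane_section",
    "wall_kinematics",
    "wall_boundary_points",
]


def _volume_ml(c, alpha: float, r: float):
    """Closed-form truncated-spheroid volume (ml) for c, r in mm."""
    c = np.asarray(c, dtype=float)
    s = np.sqrt(1.0 - (alpha * r) ** 2 / c**2)
    return np.pi * c**3 / alpha**2 * (2.0 / 3.0 + s - s**3 / 3.0) * ML_PER_MM3


@dataclass(frozen=True)
class VentricleGeometry:
    """Static shape parameters of the idealized ventricle (lengths in mm)."""

    alpha: float = 2.0                 # long-to-short-axis ratio
    r_trunc: float = 18.0              # truncation-circle radius, mm
    c_min: float = 38.0                # long axis at end systole, mm
    c_max: float = 50.0                # long axis at end diastole, mm
    v_upper: float | None = None       # fixed upper-portion cavity volume, ml
    v_total_min: float = 64.0          # printed minimum total volume, ml
    d_inlet: float = 25.0              # atrial tube diameter, mm
    d_outlet: float = 20.8             # aortic tube diameter, mm
    orifice_angle: float = 140.0       # angle between mitral and aortic axes, deg
    inlet_tube_length: float = 45.0    # mm
    outlet_tube_length: float = 35.0   # mm
    chamber_height: float = 4.0        # upper-portion transition height, mm
    outlet_root: tuple[float, float] = (-10.0, 1.0)  # aortic tube attachment, mm

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError(f"alpha must be positive, got {self.alpha}")
        if not (0 < self.r_trunc < self.c_min / self.alpha):
            raise ValueError(
                "r_trunc must satisfy 0 < r_trunc < c_min/alpha "
                f"(got r_trunc={self.r_trunc}, c_min/alpha={self.c_min / self.alpha})"
            )
        if not (self.c_min < self.c_max):
            raise ValueError("c_min must be smaller than c_max")
        if self.v_upper is None:
            v_low = float(_volume_ml(self.c_min, self.alpha, self.r_trunc))
            if self.v_total_min < v_low:
                raise ValueError(
                    f"v_total_min={self.v_total_min} ml smaller than the "
                    f"lower-portion volume {v_low:.2f} ml at c_min"
                )
            object.__setattr__(self, "v_upper", self.v_total_min - v_low)
        if self.v_upper < 0:
            raise ValueError("v_upper must be non-negative")

    # -- derived static layout of the 2-D mid-plane ------------------------
    @property
    def mitral_center_x(self) -> float:
        """Mitral channel centre; right channel wall flush with the truncation edge."""
        return self.r_trunc - self.d_inlet / 2.0

    @property
    def mitral_x_range(self) -> tuple[float, float]:
        xm = self.mitral_center_x
        return (xm - self.d_inlet / 2.0, xm + self.d_inlet / 2.0)

    @property
    def mitral_top_y(self) -> float:
        return self.chamber_height + self.inlet_tube_length

    @property
    def outlet_direction(self) -> np.ndarray:
        """Unit vector of the aortic outflow axis (tilted toward anterior)."""
        # mitral inflow axis is (0, -1); outflow axis at orifice_angle to it
        a = np.deg2rad(180.0 - self.orifice_angle)
        return np.array([-np.sin(a), np.cos(a)])


def _s_term(c: np.ndarray | float, geom: VentricleGeometry) -> np.ndarray | float:
    arg = 1.0 - (geom.alpha * geom.r_trunc) ** 2 / np.asarray(c, dtype=float) ** 2
    return np.sqrt(arg)


def _check_c(c: np.ndarray | float, geom: VentricleGeometry) -> np.ndarray:
    c = np.asarray(c, dtype=float)
    if np.any(c <= 0):
        raise ValueError("long axis c must be positive")
    if np.any(c < geom.alpha * geom.r_trunc):
        raise ValueError(
            f"c must be >= alpha*r_trunc = {geom.alpha * geom.r_trunc} mm "
            "(square-root argument non-negative)"
        )
    return c


def truncated_spheroid_volume(c, geom: VentricleGeometry = VentricleGeometry()):
    """Closed-form lower-portion cavity volume in ml for long axis ``c`` in mm."""
    c = _check_c(c, geom)
    s = _s_term(c, geom)
    bracket = 2.0 / 3.0 + s - s**3 / 3.0
    v_mm3 = np.pi * c**3 / geom.alpha**2 * bracket
    out = v_mm3 * ML_PER_MM3
    return float(out) if np.isscalar(out) or out.ndim == 0 else out


def calibrate_upper_volume(geom: VentricleGeometry) -> float:
    """Fixed upper-portion volume so the total at c_min matches v_total_min."""
    v_lower_min = float(_volume_ml(geom.c_min, geom.alpha, geom.r_trunc))
    v_up = geom.v_total_min - v_lower_min
    if v_up < 0:
        raise ValueError(
            f"v_total_min={geom.v_total_min} ml smaller than the lower-portion "
            f"volume {v_lower_min:.2f} ml at c_min"
        )
    return v_up


def total_cavity_volume(c, geom: VentricleGeometry = VentricleGeometry()):
    """Lower-portion volume plus the fixed upper-portion volume (ml)."""
    return truncated_spheroid_volume(c, geom) + geom.v_upper


def invert_volume_to_axis(
    V: float, geom: VentricleGeometry = VentricleGeometry(), tol: float = 1e-6
) -> float:
    """Long axis c (mm) with truncated_spheroid_volume(c) = V (ml).

    Monotone bracketing on [c_min, c_max] guarantees a unique root.
    """
    v_lo = truncated_spheroid_volume(geom.c_min, geom)
    v_hi = truncated_spheroid_volume(geom.c_max, geom)
    if not (v_lo - tol <= V <= v_hi + tol):
        raise ValueError(
            f"volume {V:.4f} ml outside admissible range [{v_lo:.4f}, {v_hi:.4f}] ml"
        )
    V = min(max(V, v_lo), v_hi)
    f = lambda c: truncated_spheroid_volume(c, geom) - V
    return float(brentq(f, geom.c_min, geom.c_max, xtol=1e-12, rtol=8.9e-16))


# ---------------------------------------------------------------------------
# Wall parametrization and kinematics
# ---------------------------------------------------------------------------

def _psi_trunc(c: float, geom: VentricleGeometry) -> float:
    return float(np.arccos(_s_term(c, geom)))


def wall_boundary_points(
    c: float, geom: VentricleGeometry, lam: np.ndarray
) -> np.ndarray:
    """Positions (mm) of material wall points labelled by lam in [-1, 1].

    |lam| runs from 0 at the apex to 1 at the truncation circle; the sign
    gives the side (negative x for lam < 0).  The parametrization pins the
    truncation circle (y = 0, |x| = r_trunc) for every c.
    """
    c = float(_check_c(c, geom))
    s = _s_term(c, geom)
    psi_t = _psi_trunc(c, geom)
    lam = np.asarray(lam, dtype=float)
    psi = psi_t + (1.0 - np.abs(lam)) * (np.pi - psi_t)
    x = np.sign(lam) * (c / geom.alpha) * np.sin(psi)
    y = -c * s + c * np.cos(psi)
    return np.column_stack([x, y])


def wall_kinematics(
    c: float,
    c_dot: float,
    geom: VentricleGeometry = VentricleGeometry(),
    lam: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Material boundary point positions (mm) and velocities (mm/s).

    Velocities are the exact analytic time derivatives of the positions at
    fixed material label, i.e. (dP/dc) * c_dot, with the valve plane fixed.
    """
    if not np.isfinite(c_dot):
        raise ValueError("c_dot must be finite")
    c = float(_check_c(c, geom))
    if lam is None:
        lam = np.linspace(-1.0, 1.0, 401)
    lam = np.asarray(lam, dtype=float)

    a = geom.alpha
    r = geom.r_trunc
    s = _s_term(c, geom)
    ds = (a * r) ** 2 / (c**3 * s)                      # ds/dc
    psi_t = float(np.arccos(s))
    dpsi_t = -ds / np.sqrt(1.0 - s**2)                  # d(arccos s)/dc

    frac = 1.0 - np.abs(lam)
    psi = psi_t + frac * (np.pi - psi_t)
    dpsi = (1.0 - frac) * dpsi_t                        # d psi / dc at fixed lam

    sin_psi, cos_psi = np.sin(psi), np.cos(psi)
    x = np.sign(lam) * (c / a) * sin_psi
    y = -c * s + c * cos_psi
    dx = np.sign(lam) * (sin_psi / a + (c / a) * cos_psi * dpsi)
    dy = -s - c * ds + cos_psi - c * sin_psi * dpsi

    pos = np.column_stack([x, y])
    vel = np.column_stack([dx, dy]) * c_dot
    return pos, vel


# ---------------------------------------------------------------------------
# Mid-plane section
# ---------------------------------------------------------------------------

@dataclass
class MidplaneSection:
    """2-D mid-plane cavity: closed outline plus tube/probe metadata (mm)."""

    cavity: Polygon                    # full cavity polygon
    lower_boundary: np.ndarray         # moving-wall polyline, (N, 2)
    lower_lambda: np.ndarray           # material labels of the polyline
    c: float                           # long axis this section was built at
    inlet_span: tuple[float, float]    # x-range of the mitral channel
    inlet_top_y: float                 # y of the mitral tube end
    outlet_root: np.ndarray            # aortic tube centreline start
    outlet_dir: np.ndarray             # aortic tube axis unit vector
    outlet_length: float
    outlet_width: float
    geom: VentricleGeometry = field(repr=False, default=None)

    @property
    def outline(self) -> np.ndarray:
        """Closed exterior polyline (x_mm, y_mm), first point repeated last."""
        return np.asarray(self.cavity.exterior.coords)

    def apex(self) -> np.ndarray:
        s = _s_term(self.c, self.geom)
        return np.array([0.0, -self.c * (1.0 + s)])

    def outlet_point(self, frac: float) -> np.ndarray:
        return self.outlet_root + frac * self.outlet_length * self.outlet_dir


def _lower_polygon(c: float, geom: VentricleGeometry, resolution: float):
    # choose the vertex count from the actual arc length so that spacing
    # stays below the requested resolution
    probe = wall_boundary_points(c, geom, np.linspace(-1.0, 1.0, 257))
    length = float(np.linalg.norm(np.diff(probe, axis=0), axis=1).sum())
    n = max(64, int(np.ceil(1.5 * length / resolution)))
    lam = np.linspace(-1.0, 1.0, n)
    pts = wall_boundary_points(c, geom, lam)
    return Polygon(pts), pts, lam


def midplane_section(
    c: float,
    geom: VentricleGeometry = VentricleGeometry(),
    resolution: float = 1.0,
) -> MidplaneSection:
    """Closed planar cavity outline at long axis ``c`` with tube stubs.

    The outline is the union of the truncated-spheroid lower cavity, the
    upper transition chamber, the vertical mitral (atrial) channel of width
    d_inlet and the aortic channel of width d_outlet inclined at
    ``orifice_angle`` to the mitral axis.
    """
    if resolution <= 0:
        raise ValueError("resolution must be positive")
    lower, pts, lam = _lower_polygon(c, geom, resolution)

    r = geom.r_trunc
    x_lo, x_hi = geom.mitral_x_range
    y0 = geom.chamber_height
    chamber = Polygon([(-r, 0.0), (r, 0.0), (x_hi, y0), (x_lo, y0)])
    mitral = Polygon(
        [(x_lo, y0 - 1.0), (x_hi, y0 - 1.0), (x_hi, geom.mitral_top_y), (x_lo, geom.mitral_top_y)]
    )

    root = np.asarray(geom.outlet_root, dtype=float)
    d = geom.outlet_direction
    n = np.array([d[1], -d[0]])  # unit normal to the tube axis
    hw = geom.d_outlet / 2.0
    tip = root + geom.outlet_tube_length * d
    aortic = Polygon([root - hw * n, root + hw * n, tip + hw * n, tip - hw * n])

    cavity = unary_union([lower, chamber, mitral, aortic])
    if cavity.geom_type != "Polygon":
        cavity = max(cavity.geoms, key=lambda g: g.area)
    cavity = shapely.simplify(cavity, 1e-9)
    if not cavity.is_valid or not cavity.exterior.is_simple:
        raise ValueError("cavity outline is self-intersecting")

    return MidplaneSection(
        cavity=cavity,
        lower_boundary=pts,
        lower_lambda=lam,
        c=c,
        inlet_span=(x_lo, x_hi),
        inlet_top_y=geom.mitral_top_y,
        outlet_root=root,
        outlet_dir=d,
        outlet_length=geom.outlet_tube_length,
        outlet_width=geom.d_outlet,
        geom=geom,
    )
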