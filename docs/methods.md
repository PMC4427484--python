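# Methods

This note records the model equations, the numerical scheme, the default
parameters and the design choices behind `ventriflow`, together with what the
desk-scale reduction can and cannot be expected to reproduce.

## Ventricular geometry and kinematics

The lower ventricle is a prolate spheroid of long semi-axis c and
long-to-short-axis ratio α, truncated by the mitral annulus plane where the
cross-section circle has radius r. Stacking circular cross-sections from the
apex to the truncation plane gives the closed-form cavity volume

    V(c) = (π c³/α²) [ 2/3 + s − s³/3 ],   s = √(1 − α² r²/c²).

Defaults: α = 2, r = 18 mm, c ∈ [38, 50] mm. The formula is validated against
numerical quadrature of the cross-sections to < 10⁻⁶ relative error.

The printed total cavity volumes (64 ml end-systolic, 144 ml end-diastolic,
ejection fraction 56 %) exceed what the truncated spheroid alone provides
(42.1 and 122.6 ml). We therefore model the total volume as the spheroid
volume plus a fixed upper-portion volume v_upper, calibrated once so the
total at c = 38 mm equals 64 ml (v_upper ≈ 21.94 ml). This single calibration
reproduces all three reference numbers simultaneously (V_max = 144.6 ml,
EF = 55.7 % → 56 %); whether the reference values include tube volumes is
unknowable from the outside, and any such contribution is folded into
v_upper.

Wall motion is prescribed. The truncation (valve) plane is held fixed in
space — so the valve housing and both tubes are static — and the apex
translates. Boundary material points are labelled by a normalized polar
parameter that pins the truncation circle (r = 18 mm at all times); their
velocities are the exact analytic derivatives of position at fixed label,
verified against finite differences and by re-integrating positions from
velocities (midpoint rule, error < 10⁻³ mm over diastole).

Coordinates: x toward the anatomical posterior, y from apex (negative) to
base (positive); the anterior side is x < 0. Clockwise rotation in this
frame is negative out-of-plane vorticity.

The 2-D mid-plane outline joins the truncated-spheroid section, a short
transition chamber (4 mm) above the truncation plane, a vertical atrial tube
of width 25 mm whose posterior wall is flush with the truncation edge, and
an aortic tube of width 20.8 mm inclined 40° from vertical (140° between the
orifice axes). Tube lengths (45 mm atrial, 35 mm aortic) are free choices:
long enough to decouple the boundary conditions from the valve, short enough
to fit a compact domain box. The cardiac period is quantized to whole
milliseconds (62 beats/min → 0.967 s), matching the convention of the
reference state.

## Inflow waveform

Diastole occupies T* ∈ [0, 0.65] of the cycle: E-wave on [0, 0.33],
diastasis on [0.33, 0.43], A-wave on [0.43, 0.65]. Each filling wave is a
raised-cosine-tapered (Tukey) lobe: it spans its phase window, holds the
configured peak (0.65 m/s E, 0.37 m/s A over the 25 mm inlet), and its taper
fraction is solved in closed form so the two lobes integrate to the stroke
volume V(50) − V(38) = 80.59 ml with an E:A volume split of 2.6:1. If a lobe
would need a mean below half its peak, it degenerates to a pure Hann lobe of
solved duration instead. The waveform is C¹, non-negative and zero at phase
boundaries; infeasible demands (volume beyond the rectangular bound of the
windows) are rejected with the maximum feasible volume reported.

Two windows deserve comment. Pure Hann lobes cannot carry 80.6 ml at these
peaks within any reasonable phase windows (their mean is half their peak),
which is why the flat-topped lobes are the primitive. And the A-window width
(0.22 T) is chosen so that the E-wave acceleration exceeds the A-wave
acceleration; a much shorter A-window would force a steeper A-ramp and
invert the physiological ordering of the two pressure-difference peaks.
Both windows are configurable.

The long-axis schedule c(t) inverts V(c) along the cumulative inflow
(monotone bracketing, 10⁻⁶ ml tolerance), and ċ uses the analytic dV/dc, so
wall kinematics and inflow are mutually consistent by construction: the
ventricular volume change equals the integrated transmitral flow at every
sample.

## Flow solver

Incompressible Newtonian flow (ρ = 1050 kg/m³, μ = 3.5 mPa·s, laminar) on a
staggered (MAC) grid over a 90 × 157.5 mm box; default 96 × 168 cells
(h = 0.9375 mm), dt = 0.484 ms. Time integration is first order: explicit
upwind advection and centred diffusion, then penalization, then a pressure
projection solved by direct sparse factorization, so discrete continuity
holds to round-off in every fluid cell (far below the 10⁻⁵ working
tolerance).

Two kinds of moving boundary:

* **Walls** (ventricle, chamber, tubes, housing) are excluded cells. Faces
  between fluid and wall carry the prescribed boundary velocity (nearest
  point of the moving outline; zero on static walls), entering the
  projection as known fluxes. This stair-step ghost treatment makes the
  expanding cavity pump exactly: the discrete wall flux matches the polygon
  area sweep rate to well under 2 % of the peak inflow (measured
  ≈ 2 × 10⁻⁴ m²/s at the coarse 48 × 84 grid against a 1.6 × 10⁻² m²/s peak
  flux bound of 3.3 × 10⁻⁴).
* **Leaflets** are Brinkman-penalized inside the projection domain: an
  implicit volumetric drag relaxes fluid toward the rigid-body velocity over
  the penalization time η = 10⁻⁴ s, and the projection uses a
  permeability-weighted Laplacian whose face coefficient is 1/(1 + dt/η)
  inside the plates. Without the weighting, the pressure correction pushes
  flow back through a thin plate and the interior slip saturates at
  O(dt |∇p|/ρ); with it, the slip vanishes linearly as η → 0 (verified).
  A plate thinner than a grid cell is inflated to one cell half-width for
  rasterization.

The atrial tube is capped by an inflow strip whose cells carry (0, −v_in(t));
the aortic tube ends in a strip of fixed-gauge-pressure cells (0 Pa
internally — the 110 mmHg reference is a pure offset that provably leaves
the velocity field unchanged, and is exposed as a knob for exactly that
test). The outlet strip absorbs the residual 2-D area-balance mismatch of
the planar reduction, mirroring a constant-static-pressure outlet. Inlet
velocity magnitudes are matched to the physiological peaks rather than to a
2-D flux identity; the consequence is that field magnitudes are
order-of-magnitude faithful, not quantitative.

CFL is capped at 0.7; the orchestrator halves the internal flow step (up to
16 sub-steps) when a transient jet would violate it, rather than aborting a
long run. `step()` itself still rejects CFL violations with the admissible
dt. Benchmarks: a low-Reynolds plane channel develops the Poiseuille profile
(fitted centreline/bulk ratio 1.5 to machine precision, pressure gradient
12 μ ū/W² to 0.02 %); the stair-step wall offset converges at first order
under grid refinement; kinetic energy is non-increasing without forcing.

## Leaflet dynamics

Each leaflet is a flat plate: chord 9.5 mm, thickness 0.8 mm, pivot 2.5 mm
from the outer edge, density 2000 kg/m³ (pyrolytic carbon). These dimensions
are idealizations for a 25 mm valve — the actual leaflet profile and inertia
of the modelled prosthesis are not public — and all are configurable. Pivots
sit 6.5 mm either side of the mitral channel centreline at y = 9 mm; at the
closed stop (25° from the housing plane) the leaflet tips leave a ~0.3 mm
central clearance, and the 150 μm housing clearance is represented only
geometrically, never resolved as a flow path.

With damping neglected, I θ̈ = M. The moment of inertia uses the exact
rectangle formula about the pivot (I ≈ 1.92 × 10⁻⁷ kg·m² per unit depth).
Integration is semi-implicit (new velocity first, position from the velocity
average), exact for piecewise-constant torque. Travel limits 25°–85° are
enforced by an inelastic stop (restitution 0, configurable): angle clamped,
angular velocity zeroed, pre-impact velocity recorded.

Fluid torque is evaluated as a surface-traction integral: the pressure is
sampled bilinearly on both faces of the plate at probes offset one cell
outside the rasterized solid and the pressure-jump moment is integrated
along the chord. In the penalization limit this equals the
momentum-exchange integral over the leaflet's cells; the traction form is
better conditioned for a plate thinner than the grid spacing and is directly
checkable against closed forms (uniform Δp across an end-pivoted plate gives
Δp L²/2, recovered to < 5 %; uniform pressure gives zero on any closed
body). Viscous skin friction contributes no chord-normal moment at leading
order for a thin plate and is neglected.

## Partitioned coupling

Within each time step, flow and leaflets iterate Gauss–Seidel fashion
(anterior then posterior, a fixed order for determinism): tentative angles
from the current θ̈, rasterize, advance the flow over the full dt from the
committed state, evaluate torques, under-relax θ̈, repeat. The relaxation
factor is adapted per leaflet by the scalar Aitken Δ² rule, clamped to
[0.05, 1], carried across time steps, and guarded against near-zero residual
differences. Aitken matters here: the fluid added moment of inertia of the
plate exceeds the structural one several-fold, so the unrelaxed iteration is
divergent (contraction factor ≈ −5); the Δ² update recovers the optimal
factor in two samples and the median step converges in 2–5 iterations.

Convergence is declared when the acceleration residual |M/I − θ̈| of both
leaflets falls below 10⁻³ relative to the step's peak |θ̈| (floor 1 rad/s²);
the cap is 20 iterations, after which the last iterate is committed with a
warning, matching how practical partitioned loops behave. Residual growth
beyond 10³× aborts. A leaflet resting on a stop with the torque pressing
into it is an active constraint: θ̈ = 0 and its residual is treated as
converged. The wall-pressure operator is factorized once per time step; the
leaflet-weighted operator once per coupling iteration.

## Diagnostics

Out-of-plane vorticity ω_z = ∂v/∂x − ∂u/∂y by centred differences at grid
nodes (exact for solid-body rotation and plane shear), masked inside solids.
Circulation is the vorticity integral over a region; the anterior-vortex
region is the x < 0 half of the cavity between the valve plane and
mid-depth, fixed so the sign test is deterministic (clockwise ⇒ negative).
ΔP(T*) = P_inlet − P_apex samples the gauge pressure bilinearly at the
atrial-tube entry centre and 2 mm inside the (moving) apex, with a
nearest-fluid fallback for probes caught in solid cells. Snapshots are saved
at the nearest step to each requested T* (no temporal interpolation; dt is
far below the feature time scales) — default list: T* = 0.05, 0.125, 0.2,
0.25, 0.325, 0.45, 0.55, 0.6 — as legacy-ASCII VTK structured grids plus an
npz bundle.

## Problem sizes

Default run: 96 × 168 grid, dt = 0.484 ms, ~1300 steps over diastole
(≈ 1–2 minutes on one CPU). The test suite and the travel-limit acceptance
check use a 48 × 84 grid with dt = 1.936 ms (≈ 15 s), which preserves every
qualitative feature: full opening before the E-peak, peak angular velocity
of a few tens of rad/s in the early E-wave, E-dominant ΔP with a smaller
A-wave peak, negative anterior circulation, sub-percent mass bookkeeping.

## What the desk scale does and does not show

The planar reduction preserves the mechanism chain — jet formation through
the three-channel valve, flow separation at the sudden expansion near the
aortic root, growth of the clockwise anterior vortex, leaflet entrainment by
its low-pressure core — and the analytic chain (volumes, EF, waveform) is
quantitative. It does not reproduce 3-D magnitudes: jet speeds,
pressure-difference extrema and impact velocities are order-of-magnitude
only. Two specific departures worth knowing:

* the anterior leaflet, entrained by the anterior vortex, swings well below
  full opening (to ~50°) during E-deceleration and diastasis before the
  A-wave reopens it; in 3-D the same entrainment exists but is weaker, and
  the leaflet stays near the stop. The posterior leaflet stays near-open
  through diastasis in both.
* per-step coupling occasionally hits the iteration cap during the fastest
  transients at coarse resolution (a few % of steps); the committed iterates
  keep the trajectories smooth and reruns are bit-identical.

Turbulence (peak Re ≈ 4000 is treated as laminar here as in the reference
setting), hinge micro-flow, leaflet flexibility, the aortic valve, atrial
flow structure and systole are out of scope.
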