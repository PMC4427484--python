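# ventriflow

Desk-scale fluid–structure-interaction model of diastolic left-ventricular
filling through a bileaflet mechanical heart valve (BMHV) implanted at the
mitral position.

After mitral valve replacement, the two rigid pyrolytic-carbon leaflets of a
BMHV are driven open by the transmitral jet, and the intraventricular flow
reorganizes into a dominant clockwise anterior vortex that redirects blood
toward the outflow tract. `ventriflow` reproduces this system at desk scale
for method development and teaching: an idealized beating ventricle, a
physiological biphasic inflow, a 2-D incompressible flow solver on the valve
mid-plane, and rigid-leaflet rotation coupled to the flow by a partitioned
iteration.

## Model

**Ventricle.** The lower ventricle is a truncated prolate spheroid with
long-to-short-axis ratio α = 2, truncation-circle radius r = 18 mm, and long
axis c(t) ∈ [38, 50] mm over diastole. Its cavity volume has the closed form

    V(c) = (π c³ / α²) [ 2/3 + s − s³/3 ],   s = √(1 − α² r² / c²),

and a fixed upper-portion volume (≈ 21.9 ml, calibrated so the total
end-systolic volume is 64 ml) brings the end-diastolic total to ≈ 144.6 ml —
an ejection fraction of 56 %. The wall motion is prescribed: the valve plane
stays fixed and the spheroid inflates toward the apex.

**Inflow.** Diastole at 62 beats/min (period 0.967 s) consists of an E-wave,
diastasis, and an A-wave. Each filling wave is a raised-cosine-tapered lobe
with peak inlet velocities 0.65 m/s (E) and 0.37 m/s (A); the lobe tapers are
solved in closed form so the integral of Q(t) equals the stroke volume given
by V(c). The long-axis schedule c(t) follows by inverting V along the
cumulative inflow, so dV/dt is exactly the transmitral flow rate.

**Flow.** Blood is laminar and Newtonian (ρ = 1050 kg/m³, μ = 3.5 mPa·s).
The mid-plane flow is solved on a staggered Cartesian grid with a first-order
projection scheme; the moving wall is a stair-step boundary with prescribed
face fluxes (exact discrete mass bookkeeping), the leaflets are Brinkman-
penalized rigid plates, and the aortic outlet holds a constant reference
pressure.

**Leaflets.** Each leaflet is a flat plate (chord 9.5 mm, thickness 0.8 mm)
rotating about a fixed pivot; with hinge damping neglected its equation of
motion is I θ̈ = M(flow). The opening angle is constrained to 25°–85° by an
inelastic stop. Flow and leaflets are coupled each time step by Gauss–Seidel
sub-iterations with per-leaflet Aitken Δ² relaxation of

    θ̈ᵏ⁺¹ = θ̈ᵏ + ωᵏ ( Mᵏ/I − θ̈ᵏ ),

which handles the strong added-mass feedback of light leaflets in blood.

## Worked example

```python
from ventriflow import (VentricleGeometry, total_cavity_volume,
                        truncated_spheroid_volume, DiastoleSchedule,
                        build_inflow, cycle_period)

geom = VentricleGeometry()
T = cycle_period(62)
v_min = total_cavity_volume(geom.c_min, geom)
v_max = total_cavity_volume(geom.c_max, geom)
sv = (truncated_spheroid_volume(geom.c_max, geom)
      - truncated_spheroid_volume(geom.c_min, geom))
wave = build_inflow(DiastoleSchedule(), sv, geom.d_inlet)

print(f"cardiac period          : {T:.3f} s")
print(f"end-systolic volume     : {v_min:.1f} ml")
print(f"end-diastolic volume    : {v_max:.1f} ml")
print(f"ejection fraction       : {100 * (v_max - v_min) / v_max:.1f} %")
print(f"diastolic stroke volume : {sv:.1f} ml")
print(f"peak E-wave velocity    : {wave.v_inlet.max():.2f} m/s")
print(f"diastolic uptake        : {wave.total_volume_ml:.1f} ml")
```

prints

```
cardiac period          : 0.967 s
end-systolic volume     : 64.0 ml
end-diastolic volume    : 144.6 ml
ejection fraction       : 55.7 %
diastolic stroke volume : 80.6 ml
peak E-wave velocity    : 0.65 m/s
diastolic uptake        : 80.6 ml
```

The period, volumes and ejection fraction are the healthy-subject reference
state of the model; the inflow generator hits the configured velocity peaks
while taking up exactly the stroke volume implied by the wall motion.

A full coupled run (a minute or two at the default 96×168 grid):

```bash
ventriflow run --out results/run            # all defaults
ventriflow traces --run results/run         # four-panel trace figure
ventriflow snapshot --run results/run --tstar 0.25
```

`results/run/traces.csv` holds the leaflet angles/angular velocities, the
inlet-to-apex pressure difference ΔP(T*), and the anterior circulation. In
the default run both leaflets reach the 85° stop early in the E-wave (peak
leaflet angular velocity ≈ 30 rad/s near T* ≈ 0.07), the pressure difference
peaks during rapid filling with a smaller secondary peak during atrial
systole, and the anterior circulation is negative — the clockwise anterior
vortex that dominates diastolic BMHV inflow.

A run can be configured through a single YAML document; see
`ventriflow validate` for the fully resolved defaults, and
`ventriflow fixtures --name channel_benchmark` for the seconds-scale
benchmark problems (Poiseuille channel, scripted-torque leaflet, coarse
diastole).

## Limitations

The solver is a 2-D mid-plane reduction: volumes and ejection fraction are
handled analytically, but 3-D field magnitudes (jet speeds, pressure-difference
extrema) are order-of-magnitude rather than quantitative. Hinge micro-flow,
turbulence, the aortic valve and systole are out of scope. See
`docs/methods.md` for the numerical choices and their consequences.
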