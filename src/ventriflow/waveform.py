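"""Diastolic transmitral inflow waveform and the consistent long-axis schedule.

Diastole is split into rapid filling (E-wave), diastasis and atrial systole
(A-wave), located by fractions of the cardiac period T (normalized time
T* = t/T).  Each filling wave is a smooth raised-cosine-tapered (Tukey) lobe
spanning its phase window: the peak inlet velocity is held at the configured
value (0.65 m/s E-wave, 0.37 m/s A-wave by default) and the taper fraction is
solved in closed form so that the two lobes together integrate to the
prescribed stroke volume.  When a lobe needs a mean below half its peak, it
degenerates gracefully to a pure Hann lobe of solved duration.  The waveform
is C^1, non-negative, and vanishes at the phase boundaries.

The long-axis trajectory c(t) follows by inverting the truncated-spheroid
volume along the cumulative inflow, so that dV/dt equals the transmitral
flow rate exactly (mass bookkeeping without a leak term).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import (
    VentricleGeometry,
    invert_volume_to_axis,
    truncated_spheroid_volume,
    _s_term,
)

__all__ = [
    "DiastoleSchedule",
    "InflowWaveform",
    "cycle_period",
    "build_inflow",
    "axis_trajectory",
    "dvolume_dc",
]


def cycle_period(heart_rate: float) -> float:
    """Cardiac period in seconds (60/heart_rate), quantized to whole milliseconds.

    The period is truncated (not rounded) to the millisecond, the convention
    under which 62 beats/min gives 0.967 s.
    """
    if heart_rate <= 0:
        raise ValueError("heart_rate must be positive")
    return np.floor(60.0 / heart_rate * 1000.0 + 1e-9) / 1000.0


@dataclass(frozen=True)
class DiastoleSchedule:
    """Timing and peak-velocity parameters of the diastolic filling waves."""

    heart_rate: float = 62.0        # beats/min
    v_peak_E: float = 0.65          # m/s
    v_peak_A: float = 0.37          # m/s
    e_end: float = 0.33             # T* at end of E-wave window
    diastasis_end: float = 0.43     # T* at end of diastasis
    a_end: float = 0.65             # T* at end of A-wave window (end of diastole)
    ea_volume_ratio: float = 2.6    # E:A filling-volume split

    def __post_init__(self) -> None:
        if self.heart_rate <= 0:
            raise ValueError("heart_rate must be positive")
        if not (0.0 < self.e_end <= self.diastasis_end <= self.a_end <= 1.0):
            raise ValueError(
                "phase fractions must satisfy 0 < e_end <= diastasis_end <= a_end <= 1"
            )
        if self.v_peak_E <= 0 or self.v_peak_A <= 0:
            raise ValueError("peak velocities must be positive")
        if self.ea_volume_ratio <= 0:
            raise ValueError("ea_volume_ratio must be positive")

    @property
    def period_T(self) -> float:
        return cycle_period(self.heart_rate)

    @property
    def diastole_duration(self) -> float:
        return self.a_end * self.period_T


@dataclass(frozen=True)
class _Pulse:
    """One filling wave: Tukey lobe of peak ``v_peak`` on [t0, t0 + d]."""

    t0: float
    d: float
    v_peak: float
    taper: float  # taper fraction beta in (0, 1]; 1 -> Hann

    def velocity(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        tau = t - self.t0
        out = np.zeros_like(tau)
        inside = (tau >= 0.0) & (tau <= self.d)
        ell = 0.5 * self.taper * self.d
        ti = tau[inside]
        ramp_up = ti < ell
        ramp_dn = ti > self.d - ell
        vals = np.ones_like(ti)
        vals[ramp_up] = 0.5 * (1.0 - np.cos(np.pi * ti[ramp_up] / ell))
        vals[ramp_dn] = 0.5 * (1.0 - np.cos(np.pi * (self.d - ti[ramp_dn]) / ell))
        out[inside] = self.v_peak * vals
        return out

    @property
    def volume_per_area(self) -> float:
        """Integral of the velocity lobe (m); volume = this times inlet area."""
        return self.v_peak * self.d * (1.0 - 0.5 * self.taper)


def _solve_pulse(t0: float, window: float, v_peak: float, vol_per_area: float) -> _Pulse:
    """Pulse with given integral: taper solved on the full window, or a Hann
    lobe of solved duration when the required mean is below half the peak."""
    ratio = vol_per_area / (v_peak * window)
    if ratio > 1.0 + 1e-12:
        raise ValueError("pulse volume exceeds the rectangular bound")
    if ratio >= 0.5:
        return _Pulse(t0=t0, d=window, v_peak=v_peak, taper=2.0 * (1.0 - ratio))
    return _Pulse(t0=t0, d=2.0 * vol_per_area / v_peak, v_peak=v_peak, taper=1.0)


@dataclass
class InflowWaveform:
    """Sampled transmitral inflow plus the closed-form pulse description."""

    schedule: DiastoleSchedule
    pulses: tuple[_Pulse, _Pulse]
    inlet_area_m2: float
    t: np.ndarray          # s, from 0 to end of diastole
    dt: float

    def velocity(self, t) -> np.ndarray:
        """Inlet velocity (m/s) at arbitrary times (closed form, not interpolated)."""
        t = np.asarray(t, dtype=float)
        return self.pulses[0].velocity(t) + self.pulses[1].velocity(t)

    def flow_ml_s(self, t) -> np.ndarray:
        return self.velocity(t) * self.inlet_area_m2 * 1e6

    @property
    def t_star(self) -> np.ndarray:
        return self.t / self.schedule.period_T

    @property
    def v_inlet(self) -> np.ndarray:
        return self.velocity(self.t)

    @property
    def Q_ml_s(self) -> np.ndarray:
        return self.flow_ml_s(self.t)

    @property
    def total_volume_ml(self) -> float:
        """Exact diastolic volume uptake of the closed-form pulses."""
        return sum(p.volume_per_area for p in self.pulses) * self.inlet_area_m2 * 1e6


def build_inflow(
    schedule: DiastoleSchedule,
    stroke_volume: float,
    d_inlet: float = 25.0,
    dt: float = 0.484e-3,
) -> InflowWaveform:
    """Construct the two-lobe diastolic inflow Q(t) and inlet velocity trace.

    Parameters
    ----------
    stroke_volume : float
        Diastolic volume uptake in ml; the lobe tapers/durations are solved so
        the integral matches it exactly while the peaks stay at the configured
        E/A values.
    d_inlet : float
        Atrial tube diameter in mm (velocity = Q / inlet area).
    dt : float
        Sampling interval in seconds.
    """
    if stroke_volume <= 0:
        raise ValueError("stroke_volume must be positive")
    T = schedule.period_T
    area = np.pi * (d_inlet * 1e-3 / 2.0) ** 2  # m^2
    sv_m3 = stroke_volume * 1e-6

    w_e = schedule.e_end * T
    w_a = (schedule.a_end - schedule.diastasis_end) * T
    v_e = sv_m3 * schedule.ea_volume_ratio / (1.0 + schedule.ea_volume_ratio)
    v_a = sv_m3 / (1.0 + schedule.ea_volume_ratio)

    vmax = area * (schedule.v_peak_E * w_e + schedule.v_peak_A * w_a)
    try:
        pulse_e = _solve_pulse(0.0, w_e, schedule.v_peak_E, v_e / area)
        pulse_a = _solve_pulse(schedule.diastasis_end * T, w_a, schedule.v_peak_A, v_a / area)
    except ValueError as exc:
        raise ValueError(
            f"infeasible waveform: stroke volume {stroke_volume:.1f} ml with the "
            f"configured peaks and phase windows; maximum feasible volume is "
            f"{vmax * 1e6:.1f} ml"
        ) from exc

    n = int(np.ceil(schedule.diastole_duration / dt)) + 1
    t = np.arange(n) * dt
    return InflowWaveform(
        schedule=schedule, pulses=(pulse_e, pulse_a), inlet_area_m2=area, t=t, dt=dt
    )


def dvolume_dc(c, geom: VentricleGeometry = VentricleGeometry()):
    """Analytic derivative of the truncated-spheroid volume, ml per mm."""
    c = np.asarray(c, dtype=float)
    s = _s_term(c, geom)
    ds = (geom.alpha * geom.r_trunc) ** 2 / (c**3 * s)
    bracket = 2.0 / 3.0 + s - s**3 / 3.0
    dv_mm3 = np.pi / geom.alpha**2 * (3.0 * c**2 * bracket + c**3 * (1.0 - s**2) * ds)
    out = dv_mm3 * 1e-3
    return float(out) if out.ndim == 0 else out


@dataclass
class AxisTrajectory:
    """Long-axis schedule c(t) consistent with the inflow waveform."""

    t: np.ndarray
    c_mm: np.ndarray
    c_dot_mm_s: np.ndarray
    volume_ml: np.ndarray


def axis_trajectory(
    wave: InflowWaveform, geom: VentricleGeometry = VentricleGeometry()
) -> AxisTrajectory:
    """c(t) such that the lower-cavity volume follows the integrated inflow.

    c is obtained by monotone inversion of the closed-form volume;
    c_dot = Q / (dV/dc) uses the analytic volume derivative, so velocities
    are exact time derivatives of the positions for the sampled schedule.
    """
    from scipy.integrate import cumulative_trapezoid

    v0 = truncated_spheroid_volume(geom.c_min, geom)
    v_hi = truncated_spheroid_volume(geom.c_max, geom)
    vol = v0 + cumulative_trapezoid(wave.Q_ml_s, wave.t, initial=0.0)
    if vol.max() > v_hi + 0.5:
        raise ValueError(
            f"integrated inflow {vol.max() - v0:.2f} ml exceeds the Eq-1 range "
            f"{v_hi - v0:.2f} ml"
        )
    c = np.array([invert_volume_to_axis(v, geom, tol=1e-3) for v in vol])
    c_dot = wave.Q_ml_s / dvolume_dc(c, geom)
    return AxisTrajectory(t=wave.t, c_mm=c, c_dot_mm_s=c_dot, volume_ml=vol)
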