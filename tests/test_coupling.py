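"""Gauss-Seidel/Aitken coupling: relaxation algebra, stub harness, full step."""

import warnings

import numpy as np
import pytest

from ventriflow.coupling import (
    CouplingState,
    FsiParams,
    aitken_omega,
    fsi_timestep,
    relaxed_update,
    run_diastole,
)
from ventriflow.fixtures import channel_masks
from ventriflow.fluid import FlowField, Grid
from ventriflow.leaflets import LeafletState


class TestRelaxedUpdate:
    def test_unrelaxed_returns_torque_over_inertia(self):
        assert relaxed_update(3.0, 10.0, 2.0, omega=1.0) == 5.0

    def test_half_relaxation_arithmetic(self):
        assert relaxed_update(0.0, 2.0, 1.0, omega=0.5) == 1.0

    def test_fixed_point_unchanged(self):
        for omega in (0.1, 0.5, 1.0):
            assert relaxed_update(4.0, 8.0, 2.0, omega=omega) == 4.0

    def test_validation(self):
        with pytest.raises(ValueError):
            relaxed_update(0.0, 1.0, 1.0, omega=0.0)
        with pytest.raises(ValueError):
            relaxed_update(0.0, 1.0, -1.0, omega=0.5)


class TestAitken:
    def test_guard_on_equal_residuals(self):
        assert aitken_omega(0.3, 0.3, 0.42) == 0.42

    def test_clamped_to_omega_max(self):
        # a proposal far above 1 is clamped
        assert aitken_omega(-0.27, 1.0, 2.9) == 1.0

    def test_clamped_to_omega_min(self):
        assert aitken_omega(1.0001, 1.0, 0.5, omega_min=0.05) == 0.05

    @pytest.mark.parametrize("a", [-5.0, -0.8, 0.5, 0.9])
    def test_linear_map_converges_geometrically(self, a):
        # scalar fixed-point map x <- a x + b: residual r = (a-1) x + b.
        # Aitken recovers the optimal factor and converges in a few steps even
        # for strongly divergent unrelaxed maps (a = -5, added-mass regime)
        b = 2.0
        x_star = b / (1.0 - a)
        x, omega, r_prev = 0.0, 0.5, None
        for k in range(1, 30):
            g = a * x + b
            r = g - x
            if abs(r) < 1e-12 * max(1.0, abs(x)):
                break
            if r_prev is not None:
                # the scalar harness may over-relax: for contractive maps the
                # optimal factor 1/(1-a) exceeds 1
                omega = aitken_omega(r, r_prev, omega, omega_min=1e-4, omega_max=20.0)
            x = x + omega * r
            r_prev = r
        assert k <= 10
        assert x == pytest.approx(x_star, abs=1e-9)

    def test_aitken_beats_fixed_relaxation_on_random_linear_maps(self, rng):
        def iterations(a, b, adaptive):
            x, omega, r_prev = 0.0, 0.3, None
            for k in range(1, 201):
                r = (a * x + b) - x
                if abs(r) < 1e-10 * max(1.0, abs(x)):
                    return k
                if adaptive and r_prev is not None:
                    omega = aitken_omega(r, r_prev, omega, omega_min=1e-4)
                x += omega * r
                r_prev = r
            return 201

        n_ait, n_fix = [], []
        for _ in range(50):
            a = rng.uniform(-0.95, 0.95)
            b = rng.uniform(-2, 2)
            n_ait.append(iterations(a, b, True))
            n_fix.append(iterations(a, b, False))
        assert np.mean(n_ait) < np.mean(n_fix)


def _stub_setup(n=16):
    width, length = 0.010, 0.040
    h = width / n
    grid = Grid(nx=int(round(length / h)) + 2, ny=n + 2, h=h, x0=-h, y0=-h)
    masks = channel_masks(grid, length, width, inlet_speed=0.0)
    flow = FlowField.quiescent(grid)
    leaflets = [
        LeafletState(label="anterior", pivot=(10.0, 5.0), hand=+1, theta=40.0,
                     theta_min=0.0, theta_max=180.0),
        LeafletState(label="posterior", pivot=(30.0, 5.0), hand=-1, theta=40.0,
                     theta_min=0.0, theta_max=180.0),
    ]
    return flow, leaflets, masks.wall


class TestFsiTimestepStub:
    def test_zero_torque_at_rest_is_fixed_point(self):
        flow, leaflets, wall = _stub_setup()
        cpl = CouplingState()
        torque = lambda f, lf, m: 0.0
        f2, lf2, out = fsi_timestep(
            flow, leaflets, cpl, 1e-3, wall, torque_fn=torque, advance_flow=False
        )
        assert out.k == 1 and out.converged
        for a, b in zip(leaflets, lf2):
            assert b.theta == a.theta and b.theta_dot == 0.0

    def test_linear_stub_converges_to_fixed_point(self):
        # torque linear in theta_ddot: M = I (a x + b) with |a| > 1 requires
        # the relaxed iteration; fixed point x* = b / (1 - a)
        a, b = -4.0, 100.0
        flow, leaflets, wall = _stub_setup()
        cpl = CouplingState()
        torque = lambda f, lf, m: lf.I_moment * (a * lf.theta_ddot + b)
        _, lf2, out = fsi_timestep(
            flow, leaflets, cpl, 1e-3, wall, torque_fn=torque, advance_flow=False
        )
        assert out.converged and out.k <= 10
        for lf in lf2:
            assert lf.theta_ddot == pytest.approx(b / (1 - a), rel=1e-2)

    def test_idempotent_past_convergence(self):
        a, b = 0.5, 40.0
        torque = lambda f, lf, m: lf.I_moment * (a * lf.theta_ddot + b)
        results = []
        for max_iters in (20, 40):
            flow, leaflets, wall = _stub_setup()
            cpl = CouplingState(max_iters=max_iters)
            _, lf2, _ = fsi_timestep(
                flow, leaflets, cpl, 1e-3, wall, torque_fn=torque, advance_flow=False
            )
            results.append([lf.theta_ddot for lf in lf2])
        assert results[0] == results[1]

    def test_divergence_aborts(self):
        flow, leaflets, wall = _stub_setup()
        cpl = CouplingState(omega=np.array([1.0, 1.0]), omega_min=1.0, omega_max=1.0)
        torque = lambda f, lf, m: lf.I_moment * (-50.0 * lf.theta_ddot + 1e4)
        with pytest.raises(RuntimeError, match="diverging"):
            fsi_timestep(
                flow, leaflets, cpl, 1e-3, wall,
                FsiParams(divergence_factor=10.0),
                torque_fn=torque, advance_flow=False,
            )

    def test_nonconvergence_commits_with_warning(self):
        flow, leaflets, wall = _stub_setup()
        cpl = CouplingState(max_iters=3, omega=np.array([0.05, 0.05]),
                            omega_min=0.05, omega_max=0.05)
        torque = lambda f, lf, m: lf.I_moment * (0.999 * lf.theta_ddot + 50.0)
        with pytest.warns(RuntimeWarning, match="not converged"):
            _, _, out = fsi_timestep(
                flow, leaflets, cpl, 1e-3, wall, torque_fn=torque, advance_flow=False
            )
        assert not out.converged

    def test_pinned_leaflet_counts_as_converged(self):
        flow, leaflets, wall = _stub_setup()
        for lf in leaflets:
            lf.theta, lf.theta_max = 85.0, 85.0
        cpl = CouplingState()
        torque = lambda f, lf, m: 1e-3  # keeps pressing into the stop
        _, lf2, out = fsi_timestep(
            flow, leaflets, cpl, 1e-3, wall, torque_fn=torque, advance_flow=False
        )
        assert out.k == 1 and out.converged
        for lf in lf2:
            assert lf.theta == 85.0 and lf.theta_dot == 0.0


class TestRunDeterminism:
    CFG = {
        "fluid": {"nx": 48, "ny": 84, "h_mm": 1.875, "dt_ms": 1.936},
        "geometry": {"resolution_mm": 1.5},
        "output": {"end_tstar": 0.03, "snapshot_t_stars": [0.02]},
    }

    def test_bit_identical_reruns(self):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            s1 = run_diastole(self.CFG)
            s2 = run_diastole(self.CFG)
        assert np.array_equal(s1.theta["anterior"], s2.theta["anterior"])
        assert np.array_equal(s1.theta["posterior"], s2.theta["posterior"])
        assert np.array_equal(s1.delta_p, s2.delta_p)
        snap1 = s1.snapshots[0.02]
        snap2 = s2.snapshots[0.02]
        for name in snap1:
            assert np.array_equal(snap1[name], snap2[name])
        assert s1.meta["config_hash"] == s2.meta["config_hash"]


class TestFullRunProperties:
    def test_leaflets_fully_open_during_rapid_filling(self, coarse_run):
        s = coarse_run
        ew = s.t_star < 0.33
        for label in ("anterior", "posterior"):
            assert s.theta[label][ew].max() == pytest.approx(85.0)

    def test_travel_limits_respected_throughout(self, coarse_run):
        for label in ("anterior", "posterior"):
            th = coarse_run.theta[label]
            assert th.min() >= 25.0 - 1e-9
            assert th.max() <= 85.0 + 1e-9

    def test_full_opening_precedes_inflow_peak(self, coarse_run):
        s = coarse_run
        t_peak_inflow = s.t_star[np.argmax(s.v_inlet)]
        for label in ("anterior", "posterior"):
            t_open = s.t_star[np.argmax(s.theta[label] >= 85.0 - 1e-9)]
            assert t_open < t_peak_inflow

    def test_peak_angular_velocity_in_early_e_wave(self, coarse_run):
        s = coarse_run
        om = np.maximum(np.abs(s.omega["anterior"]), np.abs(s.omega["posterior"]))
        t_pk = s.t_star[np.argmax(om)]
        assert t_pk < 0.12
        assert 5.0 < om.max() < 300.0  # O(10) rad/s

    def test_posterior_leaflet_near_open_through_diastasis(self, coarse_run):
        s = coarse_run
        dia = (s.t_star > 0.36) & (s.t_star < 0.43)
        assert s.theta["posterior"][dia].min() > 75.0

    def test_mass_balance_within_two_percent_of_peak_inflow(self, coarse_run):
        s = coarse_run
        q_peak = 0.65 * 0.025  # peak 2-D inlet flux, m^2/s
        mr = np.abs(s.mass_residual[np.isfinite(s.mass_residual)])
        assert mr.max() <= 0.02 * q_peak

    def test_pressure_difference_shape(self, coarse_run):
        s = coarse_run
        ew = s.t_star < 0.33
        aw = s.t_star > 0.43
        assert s.delta_p.max() == s.delta_p[ew].max()  # global max in E-wave
        assert 0 < s.delta_p[aw].max() < s.delta_p[ew].max()
        # driving pressure difference positive during early acceleration
        acc = (s.t_star > 0.02) & (s.t_star < 0.08)
        assert np.all(s.delta_p[acc] > 0)

    def test_clockwise_anterior_vortex(self, coarse_run):
        s = coarse_run
        k = np.argmin(np.abs(s.t_star - 0.25))
        assert s.circulation_anterior[k] < 0
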