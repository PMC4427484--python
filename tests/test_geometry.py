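"""Truncated-spheroid volume model, mid-plane section and wall kinematics."""

import numpy as np
import pytest
from scipy.integrate import quad
from shapely.geometry import LineString

from ventriflow.geometry import (
    VentricleGeometry,
    invert_volume_to_axis,
    midplane_section,
    total_cavity_volume,
    truncated_spheroid_volume,
    wall_boundary_points,
    wall_kinematics,
)


def quadrature_volume(c, alpha, r):
    """Independent oracle: stack circular cross-sections of the spheroid from
    the apex up to the truncation plane (ml)."""
    s = np.sqrt(1.0 - (alpha * r / c) ** 2)
    area = lambda z: np.pi * (c / alpha) ** 2 * (1.0 - z**2 / c**2)
    val, _ = quad(area, -c, c * s)
    return val * 1e-3


class TestVolumeModel:
    def test_closed_form_matches_quadrature_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            alpha = rng.uniform(1.2, 3.0)
            c = rng.uniform(30.0, 70.0)
            r = rng.uniform(0.2, 0.95) * c / alpha
            geom = VentricleGeometry(
                alpha=alpha, r_trunc=r, c_min=c * 0.99, c_max=c * 1.01, v_upper=0.0
            )
            v = truncated_spheroid_volume(c, geom)
            vq = quadrature_volume(c, alpha, r)
            assert abs(v - vq) / vq < 1e-6

    @pytest.mark.parametrize(
        "c, expected_ml",
        [(50.0, 122.643), (38.0, 42.057)],
    )
    def test_reference_volumes(self, c, expected_ml):
        assert truncated_spheroid_volume(c) == pytest.approx(expected_ml, abs=5e-3)

    def test_small_truncation_limit_is_full_spheroid(self):
        geom = VentricleGeometry(r_trunc=1e-6, v_upper=0.0)
        c = 50.0
        full = 4.0 / 3.0 * np.pi * (c / 2.0) ** 2 * c * 1e-3
        assert truncated_spheroid_volume(c, geom) == pytest.approx(full, rel=1e-9)

    def test_equatorial_truncation_is_half_spheroid(self):
        c, alpha = 50.0, 2.0
        geom = VentricleGeometry(r_trunc=c / alpha - 1e-9, c_min=c, c_max=c + 1, v_upper=0.0)
        half = 2.0 / 3.0 * np.pi * c**3 / alpha**2 * 1e-3
        # the 1e-9 offset keeps the constructor valid; s ~ 1e-5 remains
        assert truncated_spheroid_volume(c, geom) == pytest.approx(half, rel=1e-4)

    def test_monotone_in_c_and_r(self):
        cs = np.linspace(38.0, 50.0, 30)
        v = truncated_spheroid_volume(cs)
        assert np.all(np.diff(v) > 0)
        for r1, r2 in [(10.0, 14.0), (14.0, 18.0)]:
            g1 = VentricleGeometry(r_trunc=r1, v_upper=0.0)
            g2 = VentricleGeometry(r_trunc=r2, v_upper=0.0)
            assert truncated_spheroid_volume(44.0, g1) > truncated_spheroid_volume(44.0, g2)

    def test_bounded_by_full_spheroid(self):
        cs = np.linspace(38, 50, 13)
        v = truncated_spheroid_volume(cs)
        full = 4.0 / 3.0 * np.pi * (cs / 2.0) ** 2 * cs * 1e-3
        assert np.all(v < full)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            truncated_spheroid_volume(30.0)  # c < alpha*r_trunc = 36
        with pytest.raises(ValueError):
            truncated_spheroid_volume(-5.0)
        with pytest.raises(ValueError):
            VentricleGeometry(alpha=-1.0)
        with pytest.raises(ValueError):
            VentricleGeometry(r_trunc=25.0)  # >= c_min/alpha

    def test_total_volume_calibration(self):
        geom = VentricleGeometry()
        assert total_cavity_volume(38.0, geom) == pytest.approx(64.0, abs=1e-9)
        assert geom.v_upper == pytest.approx(21.94, abs=0.01)
        vmax = total_cavity_volume(50.0, geom)
        assert abs(vmax - 144.0) / 144.0 < 0.01

    def test_ejection_fraction_rounds_to_56_percent(self):
        geom = VentricleGeometry()
        vmin, vmax = total_cavity_volume(38.0, geom), total_cavity_volume(50.0, geom)
        assert round((vmax - vmin) / vmax * 100) == 56

    def test_stroke_volume_consistent_with_printed_range(self):
        sv = truncated_spheroid_volume(50.0) - truncated_spheroid_volume(38.0)
        assert sv == pytest.approx(80.6, abs=0.1)
        assert abs(sv - 80.0) / 80.0 < 0.01


class TestInversion:
    def test_inverse_of_quadrature_oracle(self):
        geom = VentricleGeometry()
        assert invert_volume_to_axis(quadrature_volume(50, 2, 18), geom) == pytest.approx(
            50.0, abs=1e-6
        )
        assert invert_volume_to_axis(quadrature_volume(38, 2, 18), geom) == pytest.approx(
            38.0, abs=1e-6
        )

    def test_round_trip(self, rng):
        geom = VentricleGeometry()
        cs = rng.uniform(38.0, 50.0, 100)
        for c in cs:
            v = truncated_spheroid_volume(c, geom)
            assert invert_volume_to_axis(v, geom) == pytest.approx(c, abs=1e-9)

    def test_out_of_range_reports_interval(self):
        with pytest.raises(ValueError, match=r"\["):
            invert_volume_to_axis(500.0)


class TestMidplaneSection:
    def test_outline_simple_over_diastole(self):
        geom = VentricleGeometry()
        for c in np.linspace(38.0, 50.0, 7):
            sec = midplane_section(c, geom)
            assert sec.cavity.is_valid
            assert sec.cavity.exterior.is_simple

    def test_widest_cross_section_is_short_axis(self):
        sec = midplane_section(50.0)
        w = sec.lower_boundary[:, 0]
        # the widest ventricular (lower-cavity) section is the short axis c/alpha per side
        assert w.max() == pytest.approx(25.0, abs=1e-3)
        assert w.min() == pytest.approx(-25.0, abs=1e-3)

    def test_tube_widths(self):
        geom = VentricleGeometry()
        sec = midplane_section(44.0, geom)
        assert sec.inlet_span[1] - sec.inlet_span[0] == pytest.approx(25.0)
        # chord across the aortic tube, measured away from the ventricle so
        # the probe crosses only the tube
        mid = sec.outlet_point(0.8)
        n = np.array([sec.outlet_dir[1], -sec.outlet_dir[0]])
        probe = LineString([mid - 15 * n, mid + 15 * n])
        chord = probe.intersection(sec.cavity)
        assert chord.length == pytest.approx(20.8, abs=0.2)

    def test_resolution_validation(self):
        with pytest.raises(ValueError):
            midplane_section(44.0, resolution=-1.0)

    def test_vertex_spacing_bounded(self):
        sec = midplane_section(44.0, resolution=0.5)
        pts = sec.lower_boundary
        gaps = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        assert gaps.max() <= 0.5 + 1e-9


class TestWallKinematics:
    def test_zero_rate_gives_zero_velocity(self):
        _, vel = wall_kinematics(44.0, 0.0)
        assert np.all(vel == 0.0)

    def test_velocities_match_finite_differences(self):
        c, cdot = 45.0, 12.0
        lam = np.linspace(-1, 1, 101)
        _, vel = wall_kinematics(c, cdot, lam=lam)
        d = 1e-6
        p1 = wall_boundary_points(c + d, VentricleGeometry(), lam)
        p0 = wall_boundary_points(c - d, VentricleGeometry(), lam)
        fd = (p1 - p0) / (2 * d) * cdot
        assert np.abs(fd - vel).max() < 1e-4

    def test_truncation_circle_pinned(self):
        for c in np.linspace(38, 50, 5):
            pts = wall_boundary_points(c, VentricleGeometry(), np.array([-1.0, 1.0]))
            assert pts[:, 1] == pytest.approx(0.0, abs=1e-12)
            assert np.abs(pts[:, 0]) == pytest.approx(18.0, abs=1e-9)

    def test_apex_displacement(self):
        geom = VentricleGeometry()
        apex = lambda c: wall_boundary_points(c, geom, np.array([0.0]))[0, 1]
        s = lambda c: np.sqrt(1 - (geom.alpha * geom.r_trunc / c) ** 2)
        disp = apex(38.0) - apex(50.0)
        expected = 50 * (1 + s(50)) - 38 * (1 + s(38))
        assert disp == pytest.approx(expected, abs=1e-9)

    def test_velocity_integrates_back_to_positions(self):
        # midpoint rule along a c(t) ramp reproduces the final positions
        geom = VentricleGeometry()
        lam = np.linspace(-1, 1, 51)
        t_end, n = 0.6, 6000
        dt = t_end / n
        cdot = (50.0 - 38.0) / t_end
        pos = wall_boundary_points(38.0, geom, lam).astype(float)
        for k in range(n):
            c_mid = 38.0 + cdot * (k + 0.5) * dt
            _, vel = wall_kinematics(c_mid, cdot, geom, lam)
            pos = pos + vel * dt
        final = wall_boundary_points(50.0, geom, lam)
        assert np.abs(pos - final).max() < 1e-3


class TestVolumeProperties:
    """Property-based checks of the closed-form volume."""

    from hypothesis import given, settings
    from hypothesis import strategies as st

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(
        c=st.floats(30.0, 80.0),
        alpha=st.floats(1.1, 3.0),
        frac=st.floats(0.05, 0.95),
    )
    def test_bounded_between_half_and_full_spheroid(self, c, alpha, frac):
        r = frac * c / alpha
        geom = VentricleGeometry(
            alpha=alpha, r_trunc=r, c_min=c, c_max=c + 1.0, v_upper=0.0
        )
        v = truncated_spheroid_volume(c, geom)
        full = 4.0 / 3.0 * np.pi * (c / alpha) ** 2 * c * 1e-3
        half = 2.0 / 3.0 * np.pi * c**3 / alpha**2 * 1e-3
        assert half < v < full
        # strictly increasing in the long axis
        assert truncated_spheroid_volume(c + 0.5, geom) > v
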