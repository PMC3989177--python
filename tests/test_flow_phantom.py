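"""Vessel geometry, laminar velocity field, and trajectory integration."""

import numpy as np
import pytest

import tofsim as ts
from tofsim.geometry import GeometryError, OutsideLumenError


class TestMakeGeometry:
    def test_straight_radius_profile_is_constant(self):
        g = ts.make_geometry({"kind": "straight", "diameter": 8.0, "length": 207.0})
        s = np.linspace(0, 207, 50)
        assert np.allclose(g.radius(s), 4.0)

    def test_stenosis_throat_diameter_convention(self):
        # "50 % of the diameter" halves the throat diameter
        g = ts.make_geometry(
            {"kind": "stenosed", "diameter": 8.0, "length": 207.0,
             "stenosis_fraction": 0.5}
        )
        assert g.throat_radius == pytest.approx(2.0)
        assert g.radius(g.stenosis_center) == pytest.approx(2.0)
        # taper is contained and returns to the nominal radius
        assert g.radius(0.0) == pytest.approx(4.0)
        assert g.radius(207.0) == pytest.approx(4.0)

    def test_radius_profile_is_continuous_and_positive(self):
        g = ts.make_geometry(
            {"kind": "stenosed", "diameter": 8.0, "length": 207.0,
             "stenosis_fraction": 0.75}
        )
        s = np.linspace(0, 207, 20001)
        r = g.radius(s)
        assert np.all(r > 0)
        assert np.max(np.abs(np.diff(r))) < 1e-2  # no jumps at taper edges

    @pytest.mark.parametrize(
        "spec",
        [
            {"kind": "stenosed", "diameter": 8.0, "length": 207.0,
             "stenosis_fraction": 1.0},  # closed lumen
            {"kind": "stenosed", "diameter": 8.0, "length": 207.0,
             "stenosis_fraction": 0.0},
            {"kind": "straight", "diameter": -8.0, "length": 207.0},
            {"kind": "helix", "diameter": 8.0, "length": 207.0},
            {"kind": "ubend", "diameter": 8.0, "bend_radius": 2.0},  # < radius
        ],
    )
    def test_invalid_specs_rejected(self, spec):
        with pytest.raises(GeometryError):
            ts.make_geometry(spec)

    def test_ubend_centerline_geometry(self):
        g = ts.make_geometry(
            {"kind": "ubend", "diameter": 8.0, "bend_radius": 44.0, "height": 207.0}
        )
        assert g.leg_length == pytest.approx(207.0 - 44.0)
        assert g.length == pytest.approx(2 * 163.0 + np.pi * 44.0)
        pos, tan = g.centerline(np.array([0.0, g.length]))
        # both ends at z = 0, separated by the bend diameter in x
        assert pos[0][2] == pytest.approx(0.0)
        assert pos[1][2] == pytest.approx(0.0, abs=1e-9)
        assert abs(pos[1][0] - pos[0][0]) == pytest.approx(88.0)
        # arc length parameterization: tangents are unit vectors
        s = np.linspace(0, g.length, 200)
        _, tans = g.centerline(s)
        assert np.allclose(np.linalg.norm(tans, axis=1), 1.0)


class TestAxialVelocity:
    def test_no_slip_at_the_wall(self):
        g = ts.make_geometry({"kind": "straight", "diameter": 8.0, "length": 207.0})
        ff = ts.FlowField(g, 2.5)
        theta = np.linspace(0, 2 * np.pi, 16, endpoint=False)
        pts = np.stack([4.0 * np.cos(theta), 4.0 * np.sin(theta),
                        np.full(16, 100.0)], axis=1)
        v = ff.velocity(pts * (1 - 1e-13), check=False)
        assert np.all(np.linalg.norm(v, axis=1) < 1e-9)

    def test_centerline_peak_speed(self):
        # v_max = 2 Q / (pi R^2) with Q = 2.5 ml/s and an 8 mm tube
        g = ts.make_geometry({"kind": "straight", "diameter": 8.0, "length": 207.0})
        ff = ts.FlowField(g, 2.5)
        v = ff.velocity([[0.0, 0.0, 100.0]])[0]
        assert v[2] == pytest.approx(2 * 2.5 / (np.pi * 16.0), rel=1e-12)
        assert v[2] == pytest.approx(0.09947, rel=1e-3)  # ~99.5 mm/s
        assert v[0] == v[1] == 0.0

    def test_mean_speed_quadruples_at_50pct_stenosis_throat(self):
        g = ts.make_geometry(
            {"kind": "stenosed", "diameter": 8.0, "length": 207.0,
             "stenosis_fraction": 0.5}
        )
        ff = ts.FlowField(g, 2.5)
        ratio = (np.linalg.norm(ff.velocity([[0, 0, g.stenosis_center]])[0])
                 / np.linalg.norm(ff.velocity([[0, 0, 10.0]])[0]))
        assert ratio == pytest.approx(4.0, rel=1e-9)

    def test_flux_is_conserved_through_random_cross_sections(self):
        # continuity: numerically integrated flux equals Q everywhere
        g = ts.make_geometry(
            {"kind": "stenosed", "diameter": 8.0, "length": 207.0,
             "stenosis_fraction": 0.5}
        )
        ff = ts.FlowField(g, 2.5)
        rng = np.random.default_rng(7)
        for z in rng.uniform(5.0, 202.0, 10):
            flux = _cross_section_flux(ff, z, 4.0)
            assert flux == pytest.approx(2.5, rel=5e-3)

    def test_point_outside_lumen_is_rejected(self):
        g = ts.make_geometry({"kind": "straight", "diameter": 8.0, "length": 207.0})
        ff = ts.FlowField(g, 2.5)
        with pytest.raises(OutsideLumenError):
            ff.velocity([[5.0, 0.0, 100.0]])


def _cross_section_flux(ff, z, R, n=500):
    x = np.linspace(-R, R, n)
    X, Y = np.meshgrid(x, x)
    r = np.hypot(X, Y)
    m = r < R * (1 - 1e-9)
    pts = np.stack([X[m], Y[m], np.full(int(m.sum()), z)], axis=1)
    vz = ff.velocity(pts, check=False)[:, 2]
    return vz.sum() * (x[1] - x[0]) ** 2


class TestIntegrateTrajectory:
    def test_centerline_straight_tube_constant_speed(self):
        g = ts.make_geometry({"kind": "straight", "diameter": 8.0, "length": 207.0})
        ff = ts.FlowField(g, 2.5)
        traj = ts.integrate_trajectory(ff, (0.0, 0.0), 1.0)
        assert np.allclose(traj.speeds, traj.speeds[0])
        assert np.allclose(traj.positions[:, :2], 0.0)
        # transit time = L / v_max ~ 2.08 s
        v_max = 2 * 2.5 / (np.pi * 16.0)
        assert traj.transit_time == pytest.approx(207.0 / v_max, rel=1e-3)

    def test_stenosed_tube_speed_rises_then_relaxes(self):
        g = ts.make_geometry(
            {"kind": "stenosed", "diameter": 8.0, "length": 207.0,
             "stenosis_fraction": 0.5}
        )
        ff = ts.FlowField(g, 2.5)
        traj = ts.integrate_trajectory(ff, (1.0, 0.0), 1.0)
        peak = np.argmax(traj.speeds)
        assert traj.speeds[peak] > 3.5 * traj.speeds[0]
        # monotone rise into the throat and relaxation past it (allow
        # numerical wiggle of one part in 1e6)
        upseg = traj.speeds[: peak + 1]
        downseg = traj.speeds[peak:]
        assert np.all(np.diff(upseg) >= -1e-6 * traj.speeds[peak])
        assert np.all(np.diff(downseg) <= 1e-6 * traj.speeds[peak])
        assert traj.speeds[-1] == pytest.approx(traj.speeds[0], rel=1e-3)

    def test_trajectory_speeds_match_field(self):
        g = ts.make_geometry(
            {"kind": "stenosed", "diameter": 8.0, "length": 207.0,
             "stenosis_fraction": 0.5}
        )
        ff = ts.FlowField(g, 2.5)
        v_max = np.linalg.norm(ff.velocity([[0, 0, g.stenosis_center]])[0])
        traj = ts.integrate_trajectory(ff, (0.5, 0.5), 1.0)
        probe = traj.positions[:: max(traj.n_samples // 50, 1)]
        v_field = np.linalg.norm(ff.velocity(probe, check=False), axis=1)
        v_traj = traj.speeds[:: max(traj.n_samples // 50, 1)]
        assert np.max(np.abs(v_traj - v_field)) < 0.01 * v_max

    def test_inlet_point_outside_disc_rejected(self):
        g = ts.make_geometry({"kind": "straight", "diameter": 8.0, "length": 207.0})
        ff = ts.FlowField(g, 2.5)
        with pytest.raises(OutsideLumenError):
            ts.integrate_trajectory(ff, (4.5, 0.0), 1.0)

    def test_ubend_trajectory_traverses_both_legs(self):
        g = ts.make_geometry(
            {"kind": "ubend", "diameter": 8.0, "bend_radius": 44.0, "height": 100.0}
        )
        ff = ts.FlowField(g, 2.5)
        traj = ts.integrate_trajectory(ff, (0.0, 0.0), 2.0)
        # path rises along one leg, crosses the bend, descends the other
        assert traj.positions[:, 2].max() > g.leg_length + 40.0
        assert traj.exit_position[0] == pytest.approx(88.0, abs=0.5)
        assert traj.exit_position[2] == pytest.approx(0.0, abs=0.5)
        # speed constant along the whole path (R and eta constant)
        assert np.allclose(traj.speeds, traj.speeds[0], rtol=5e-3)


class TestInterpolatePosition:
    def test_exact_at_sample_times(self):
        g = ts.make_geometry({"kind": "straight", "diameter": 8.0, "length": 207.0})
        ff = ts.FlowField(g, 2.5)
        traj = ts.integrate_trajectory(ff, (1.0, -1.0), 1.0)
        for i in (0, 5, traj.n_samples - 1):
            p = ts.interpolate_position(traj, i * traj.dt_flow)
            assert np.allclose(p, traj.positions[i])

    def test_midpoint_on_straight_path(self):
        g = ts.make_geometry({"kind": "straight", "diameter": 8.0, "length": 207.0})
        ff = ts.FlowField(g, 2.5)
        traj = ts.integrate_trajectory(ff, (0.0, 0.0), 1.0)
        p = ts.interpolate_position(traj, 0.5 * traj.dt_flow)
        assert np.allclose(p, 0.5 * (traj.positions[0] + traj.positions[1]))

    def test_matches_fine_reintegration(self):
        # refinement oracle: dense re-integration at dt/100 bounds the
        # interpolation error by dt * speed / 2
        g = ts.make_geometry(
            {"kind": "stenosed", "diameter": 8.0, "length": 207.0,
             "stenosis_fraction": 0.5}
        )
        ff = ts.FlowField(g, 2.5)
        dt = 4.0
        coarse = ts.integrate_trajectory(ff, (0.8, 0.3), dt)
        fine = ts.integrate_trajectory(ff, (0.8, 0.3), dt / 100.0)
        rng = np.random.default_rng(3)
        tmax = min(coarse.transit_time, fine.transit_time)
        v_peak = coarse.speeds.max()
        for t in rng.uniform(0, tmax, 25):
            err = np.linalg.norm(
                ts.interpolate_position(coarse, t) - ts.interpolate_position(fine, t)
            )
            assert err < dt * v_peak / 2

    def test_out_of_span_times_signal(self):
        g = ts.make_geometry({"kind": "straight", "diameter": 8.0, "length": 207.0})
        ff = ts.FlowField(g, 2.5)
        traj = ts.integrate_trajectory(ff, (0.0, 0.0), 1.0)
        with pytest.raises(ts.flow.TrajectoryWindowError):
            ts.interpolate_position(traj, -1.0)
        with pytest.raises(ts.flow.TrajectoryWindowError):
            ts.interpolate_position(traj, traj.transit_time + 1.0)


class TestTrajectoryBundle:
    def test_bundle_lookup_agrees_with_per_trajectory_interpolation(self):
        g = ts.make_geometry({"kind": "straight", "diameter": 8.0, "length": 60.0})
        ff = ts.FlowField(g, 2.5)
        seeds = ts.sunflower_points(16, 4.0 * 0.995)
        bundle = ts.trace_bundle(ff, seeds, samples_per_trajectory=200)
        rng = np.random.default_rng(11)
        idx = rng.integers(0, 16, 40)
        tau = rng.uniform(0, 100.0, 40)
        batch = bundle.positions_at(idx, tau)
        for j, (i, t) in enumerate(zip(idx, tau)):
            t_clip = min(t, bundle.trajectories[i].transit_time)
            ref = ts.interpolate_position(bundle.trajectories[i], t_clip)
            assert np.allclose(batch[j], ref)

    def test_coord_lookup_matches_full_positions(self):
        g = ts.make_geometry({"kind": "straight", "diameter": 8.0, "length": 60.0})
        ff = ts.FlowField(g, 2.5)
        seeds = ts.sunflower_points(8, 4.0 * 0.995)
        bundle = ts.trace_bundle(ff, seeds, samples_per_trajectory=150)
        idx = np.arange(8)
        tau = np.linspace(0, 50, 8)
        full = bundle.positions_at(idx, tau)
        for axis in range(3):
            assert np.allclose(bundle.coord_at(idx, tau, axis), full[:, axis])
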