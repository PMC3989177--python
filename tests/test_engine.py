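"""k-space synthesis: signal summation, line acquisition, slab loops, chunking."""

import numpy as np
import pytest

import tofsim as ts
from tofsim.engine import MovingComponent, StationaryComponent
from tofsim.flow import Trajectory, TrajectoryBundle
from tofsim.seeding import TrajectorySeeding

from conftest import make_tube_component, lumen_mask


def small_protocol(**kw):
    base = dict(
        TE=4.7, TR=40.0, flip=np.deg2rad(20), matrix=(16, 16, 4),
        fov=(32.0, 32.0, 16.0), slab_width=4.0, slice_thickness=1.0,
        readout_window=2.56,
    )
    base.update(kw)
    return ts.Protocol(**base)


def disc_component(n=600, radius=6.0, z_half=2.0, seed=0, rho=1.0, T2=170.0):
    import warnings

    rng = np.random.default_rng(seed)
    pts = []
    while len(pts) < n:
        p = rng.uniform(-radius, radius, 2)
        if np.hypot(*p) < radius:
            pts.append(p)
    pos = np.column_stack([np.array(pts), rng.uniform(-z_half, z_half, n)])
    with warnings.catch_warnings():
        # some tests use an artificially long T2 to isolate FFT symmetry
        warnings.simplefilter("ignore", UserWarning)
        tis = ts.TissueProperties(T1=850.0, T2=T2, proton_density=rho)
    return StationaryComponent(positions=pos, tissue=tis,
                               particle_volume=np.pi * radius**2 * 2 * z_half / n)


class TestSampleSignal:
    def test_single_particle_signal(self):
        c = StationaryComponent(
            positions=np.array([[0.0, 0.0, 0.0]]),
            tissue=ts.TissueProperties(T1=850, T2=170), particle_volume=1.0,
        ).make_cloud()
        c.M[0] = [1.0, 0.0, 0.3]
        assert ts.sample_signal([c]) == pytest.approx(1.0 + 0.0j)

    def test_opposite_phases_cancel(self):
        c = StationaryComponent(
            positions=np.zeros((2, 3)),
            tissue=ts.TissueProperties(T1=850, T2=170), particle_volume=2.0,
        ).make_cloud()
        c.M[0] = [0.5, 0.5, 0.0]
        c.M[1] = [-0.5, -0.5, 0.0]
        assert ts.sample_signal([c]) == pytest.approx(0.0 + 0.0j)

    def test_matches_extended_precision_summation(self):
        rng = np.random.default_rng(4)
        n = 1000
        c = StationaryComponent(
            positions=rng.normal(size=(n, 3)),
            tissue=ts.TissueProperties(T1=850, T2=170), particle_volume=1.0,
        ).make_cloud()
        c.M[:] = rng.normal(size=(n, 3))
        vols = rng.uniform(0.1, 2.0, n)
        c.volume = 1.0  # particle_volumes constant; emulate weights via M
        c.M *= vols[:, None]
        got = ts.sample_signal([c])
        want = complex(
            float(np.sum(np.asarray(c.M[:, 0], dtype=np.longdouble))),
            float(np.sum(np.asarray(c.M[:, 1], dtype=np.longdouble))),
        )
        assert abs(got - want) <= 1e-12 * abs(want)


class TestAcquireLine:
    def test_dc_line_peaks_at_echo_center(self, ):
        comp = disc_component()
        proto = small_protocol()
        cloud = comp.make_cloud()
        line = ts.acquire_line([cloud], proto, (-2.0, 2.0), 0, 0, 0.0)
        assert np.argmax(np.abs(line)) == proto.matrix[0] // 2

    def test_empty_phantom_gives_zero_line(self):
        comp = disc_component(rho=0.0)
        proto = small_protocol()
        cloud = comp.make_cloud()
        line = ts.acquire_line([cloud], proto, (-2.0, 2.0), 0, 0, 0.0)
        assert np.allclose(line, 0.0)

    def test_freshly_injected_particles_are_dark_until_next_pulse(self):
        # a particle appearing mid-line has no transverse magnetization
        comp = make_tube_component(n_traj=8, samples=200)
        proto = small_protocol(fov=(64.0, 64.0, 16.0), matrix=(16, 16, 4),
                               slab_width=4.0)
        cloud = comp.make_cloud()
        ts.acquire_line([cloud], proto, (28.0, 32.0), 0, 0, 0.0)
        cloud.replenish(proto.TR)
        fresh = cloud.entry > 0.0
        assert np.any(fresh)
        assert np.allclose(cloud.M[fresh, 0], 0.0)
        assert np.allclose(cloud.M[fresh, 1], 0.0)


class TestSimulateSlab:
    def test_zero_proton_density_gives_zero_kspace(self):
        comp = disc_component(rho=0.0)
        k = ts.simulate_slab([comp], small_protocol(), (-2.0, 2.0))
        assert np.allclose(k.data, 0.0)

    def test_kspace_of_real_object_is_conjugate_symmetric(self):
        # stationary phantom, on resonance, negligible T2 decay: after the
        # steady-state transient the k-space obeys S(-k) = -conj(S(k))
        # (the constant transverse phase of the post-pulse magnetization
        # along -y contributes a factor (-i)^2)
        comp = disc_component(T2=1e9)
        proto = small_protocol(dummy_trs=150)
        k = ts.simulate_slab([comp], proto, (-2.0, 2.0))
        d = k.data
        inner = d[1:, 1:, 1:]
        mirrored = np.conj(d[1:, 1:, 1:][::-1, ::-1, ::-1])
        assert np.max(np.abs(inner + mirrored)) < 1e-6 * np.max(np.abs(d))

    def test_linearity_in_tissue_components(self):
        a = disc_component(n=200, seed=1)
        b = disc_component(n=150, seed=2, rho=0.6)
        proto = small_protocol()
        k_ab = ts.simulate_slab([a, b], proto, (-2.0, 2.0))
        k_a = ts.simulate_slab([a], proto, (-2.0, 2.0))
        k_b = ts.simulate_slab([b], proto, (-2.0, 2.0))
        assert np.allclose(k_ab.data, k_a.data + k_b.data, atol=1e-12)

    def test_zero_velocity_flow_reproduces_stationary_result(self):
        # a "moving" cloud whose trajectories never move must match the
        # stationary-tissue result exactly
        rng = np.random.default_rng(9)
        pos = np.column_stack([rng.uniform(-5, 5, (40, 2)), rng.uniform(-2, 2, 40)])
        trajs = [
            Trajectory(
                id=i, dt_flow=1.0,
                positions=np.repeat(pos[i][None, :], 3, axis=0),
                speeds=np.zeros(3), inlet_point=np.zeros(2),
                transit_time=1e12, exit_position=pos[i],
            )
            for i in range(40)
        ]
        bundle = TrajectoryBundle(trajs)
        tissue = ts.TissueProperties(T1=850, T2=170)
        seedings = [
            TrajectorySeeding(i, inlet_area=1.0, spacing=1.0,
                              injection_interval=1e12, particle_volume=0.5)
            for i in range(40)
        ]
        moving = MovingComponent(bundle=bundle, seedings=seedings, tissue=tissue)
        stationary = StationaryComponent(positions=pos, tissue=tissue,
                                         particle_volume=0.5)
        proto = small_protocol()
        k_m = ts.simulate_slab([moving], proto, (-2.0, 2.0))
        k_s = ts.simulate_slab([stationary], proto, (-2.0, 2.0))
        assert np.allclose(k_m.data, k_s.data, atol=1e-12)

    def test_particle_count_conserved_across_a_slab(self):
        comp = make_tube_component(n_traj=8, samples=200)
        cloud = comp.make_cloud()
        base = cloud.counts_per_trajectory().copy()
        proto = small_protocol(fov=(64.0, 64.0, 16.0))
        ts.simulate_slab([comp], proto, (28.0, 32.0))  # fresh internal clouds
        for t in np.linspace(0, 50 * proto.TR, 23):
            cloud.replenish(t)
            assert np.all(np.abs(cloud.counts_per_trajectory() - base) <= 1)


class TestRunChunked:
    def test_chunked_equals_single_chunk(self, tube_component):
        proto = small_protocol(fov=(64.0, 64.0, 32.0), matrix=(16, 16, 4),
                               slab_width=4.0)
        slab = (28.0, 32.0)
        k1 = ts.run_chunked([tube_component], proto, slab, n_chunks=1)
        k4 = ts.run_chunked([tube_component], proto, slab, n_chunks=4)
        denom = np.max(np.abs(k1.data))
        assert np.max(np.abs(k1.data - k4.data)) < 1e-10 * denom

    def test_more_chunks_than_trajectories(self):
        comp = make_tube_component(n_traj=3, samples=150)
        proto = small_protocol(fov=(64.0, 64.0, 32.0))
        slab = (28.0, 32.0)
        k1 = ts.run_chunked([comp], proto, slab, n_chunks=1)
        k8 = ts.run_chunked([comp], proto, slab, n_chunks=8)
        assert np.allclose(k1.data, k8.data, atol=1e-12 * np.max(np.abs(k1.data)))

    def test_stationary_component_is_its_own_chunk(self):
        s = disc_component(n=100)
        proto = small_protocol()
        k1 = ts.run_chunked([s], proto, (-2.0, 2.0), n_chunks=1)
        k5 = ts.run_chunked([s], proto, (-2.0, 2.0), n_chunks=5)
        assert np.allclose(k1.data, k5.data)

    def test_runtime_scales_linearly_in_particle_count(self):
        # complexity trend on three sizes: time per particle roughly flat
        import time
        proto = small_protocol(fov=(64.0, 64.0, 32.0), matrix=(8, 8, 2),
                               slab_width=2.0, slice_thickness=1.0)
        slab = (29.0, 31.0)
        times, counts = [], []
        for n_traj in (8, 16, 32):
            comp = make_tube_component(n_traj=n_traj, samples=150)
            counts.append(comp.make_cloud().n_particles)
            t0 = time.perf_counter()
            ts.simulate_slab([comp], proto, slab)
            times.append(time.perf_counter() - t0)
        # quadratic scaling would give ratio ~4; allow generous headroom
        per_particle = [t / c for t, c in zip(times, counts)]
        assert per_particle[2] < 3.0 * per_particle[0] + 1e-4
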