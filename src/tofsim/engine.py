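"""k-space synthesis: advance particles on the MRA clock and accumulate signal.

The engine executes the per-TR schedule of :mod:`tofsim.sequence` on a
set of particle clouds.  Within one TR it saturates (optionally),
excites with a subdivided RF pulse, phase encodes, relaxes to the
readout window and then alternates state updates with point
acquisitions: every ``dwell = readout_window / Nx`` milliseconds the
moving particles are re-localized on their trajectories, relaxation and
off-resonance precession are applied, retired particles are replaced by
fresh unexcited ones, the frequency-encode phase advances by one k-space
step, and the volume-weighted complex signal

    S = sum_i V_i * (Mx_i + 1j * My_i)

is recorded.  One line of k-space is filled per TR.  Components (tissue
types, trajectory chunks) contribute additively, which the chunked
runner exploits: k-space is linear in the particle set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .bloch import RFPulse, rf_excite, tone_flip
from .flow import TrajectoryBundle
from .seeding import (
    MovingCloud,
    StationaryCloud,
    TissueProperties,
    TrajectorySeeding,
)
from .sequence import Protocol, presat_band, presaturate, tr_schedule

__all__ = [
    "AcquisitionClock",
    "KSpaceVolume",
    "MovingComponent",
    "StationaryComponent",
    "sample_signal",
    "acquire_line",
    "simulate_slab",
    "run_chunked",
    "default_line_order",
]


@dataclass
class AcquisitionClock:
    """MRA simulation clock; the step equals the readout dwell time."""

    dwell: float
    t: float = 0.0

    def advance(self, dt: float) -> float:
        if dt < 0:
            raise ValueError("clock must advance monotonically")
        self.t += dt
        return self.t


@dataclass
class KSpaceVolume:
    """Complex raw data of one slab, indexed (kx, ky, kz), DC at N//2."""

    data: np.ndarray
    fov: Tuple[float, float, float]
    slab: Tuple[float, float]
    meta: dict = field(default_factory=dict)

    def __add__(self, other: "KSpaceVolume") -> "KSpaceVolume":
        if self.data.shape != other.data.shape:
            raise ValueError("k-space shapes differ")
        return KSpaceVolume(
            data=self.data + other.data,
            fov=self.fov,
            slab=self.slab,
            meta=dict(self.meta),
        )


@dataclass
class MovingComponent:
    """Flowing-fluid component: a trajectory bundle plus its seeding."""

    bundle: TrajectoryBundle
    seedings: Sequence[TrajectorySeeding]
    tissue: TissueProperties
    flow_sign: int = 1  # +1 flows along +z (co-flow), -1 against it

    def make_cloud(self, t0: float = 0.0, traj_subset=None) -> MovingCloud:
        if traj_subset is None:
            cloud = MovingCloud(self.bundle, self.seedings, self.tissue, t0=t0)
        else:
            idx = list(traj_subset)
            sub_bundle = TrajectoryBundle([self.bundle.trajectories[i] for i in idx])
            sub_seed = [
                TrajectorySeeding(
                    trajectory_id=k,
                    inlet_area=self.seedings[i].inlet_area,
                    spacing=self.seedings[i].spacing,
                    injection_interval=self.seedings[i].injection_interval,
                    particle_volume=self.seedings[i].particle_volume,
                )
                for k, i in enumerate(idx)
            ]
            cloud = MovingCloud(sub_bundle, sub_seed, self.tissue, t0=t0)
        cloud.flow_sign = self.flow_sign
        return cloud

    @property
    def n_trajectories(self) -> int:
        return len(self.bundle)


@dataclass
class StationaryComponent:
    """Stationary tissue component (positions fixed for the whole scan)."""

    positions: np.ndarray
    tissue: TissueProperties
    particle_volume: float

    def make_cloud(self, t0: float = 0.0) -> StationaryCloud:
        cloud = StationaryCloud(self.positions, self.tissue, self.particle_volume)
        cloud.flow_sign = 1
        return cloud


def sample_signal(clouds) -> complex:
    """Volume-weighted sum of transverse magnetization over all particles."""
    s = 0.0 + 0.0j
    for cloud in clouds:
        if cloud.n_particles == 0:
            continue
        v = cloud.particle_volumes
        s += complex(np.dot(v, cloud.M[:, 0]), np.dot(v, cloud.M[:, 1]))
    return s


# -- in-place fast paths (the bloch module's operators copy) -----------------


def _relax_inplace(M, e1: float, e2: float, m0: float) -> None:
    M[:, 0] *= e2
    M[:, 1] *= e2
    M[:, 2] *= e1
    M[:, 2] += m0 * (1.0 - e1)


def _precess_inplace(M, angle) -> None:
    c = np.cos(angle)
    s = np.sin(angle)
    mx = M[:, 0] * c - M[:, 1] * s
    M[:, 1] *= c
    M[:, 1] += M[:, 0] * s
    M[:, 0] = mx


def _apply_rf(cloud, protocol: Protocol, slab, t_start: float) -> None:
    z_lo, z_hi = slab
    n_sub = (
        protocol.rf_substeps_moving if cloud.is_moving
        else protocol.rf_substeps_stationary
    )
    pulse = RFPulse(
        flip=protocol.flip,
        phase=0.0,
        duration=protocol.rf_duration,
        n_substeps=n_sub,
    )
    sign = getattr(cloud, "flow_sign", 1)
    flip_fn = None
    if protocol.tone_enabled:
        flip_fn = lambda pos: tone_flip(
            protocol.flip, np.clip(pos[:, 2], z_lo, z_hi),
            (z_lo, z_hi), protocol.tone_span, flow_direction=sign,
        )
    # pre-fetch z at all substep midpoints in one batched lookup; only z
    # matters for the slab profile and the TONE ramp
    tau_sub = protocol.rf_duration / n_sub
    t_mids = t_start + (np.arange(n_sub) + 0.5) * tau_sub
    z_mids = cloud.coord_at(t_mids, 2)  # (N, n_sub)

    def _z_positions(t):
        k = int(round((t - t_start) / tau_sub - 0.5))
        pos = np.zeros((cloud.n_particles, 3))
        pos[:, 2] = z_mids[:, k]
        return pos

    cloud.M = rf_excite(
        cloud.M,
        pulse,
        delta_omega=cloud.tissue.chemical_shift,
        position_provider=_z_positions,
        in_profile=lambda pos: (pos[:, 2] >= z_lo) & (pos[:, 2] <= z_hi),
        flip_of_position=flip_fn,
        t_start=t_start,
    )


def _apply_phase_encode(cloud, protocol: Protocol, slab, ky: int, kz: int,
                        t_encode: float, t_echo: float) -> None:
    # with flow compensation the moment-nulled encode gradients register the
    # particle position at the echo; without it, at the encode instant
    t_y = t_echo if protocol.flow_comp[1] else t_encode
    t_z = t_echo if protocol.flow_comp[2] else t_encode
    y = cloud.coord_at(np.float64(t_y), 1)
    z = cloud.coord_at(np.float64(t_z), 2)
    z_c = 0.5 * (slab[0] + slab[1])
    angle = -2.0 * np.pi * (
        ky * (y - protocol.fov_center[1]) / protocol.fov[1]
        + kz * (z - z_c) / protocol.slab_width
    )
    _precess_inplace(cloud.M, angle)


def acquire_line(
    clouds,
    protocol: Protocol,
    slab: Tuple[float, float],
    ky: int,
    kz: int,
    t_tr: float,
) -> np.ndarray:
    """Execute one TR starting at absolute time ``t_tr``; return Nx samples.

    Mutates the clouds' magnetization state (they carry it to the next
    TR, as on a real scanner).
    """
    tr_schedule(protocol, slab, ky, kz)  # validates timing and indices
    nx = protocol.matrix[0]
    dwell = protocol.dwell
    tau = protocol.rf_duration
    echo = tau / 2.0 + protocol.TE
    t_window = echo - (nx // 2) * dwell
    samples = np.zeros(nx, dtype=complex)

    for cloud in clouds:
        cloud.replenish(t_tr)
    if protocol.presat_enabled:
        presaturate(list(clouds), presat_band(protocol, slab), t_tr)
    for cloud in clouds:
        _apply_rf(cloud, protocol, slab, t_tr)
    for cloud in clouds:
        _apply_phase_encode(cloud, protocol, slab, ky, kz,
                            t_tr + tau, t_tr + echo)
    # free relaxation from the end of the pulse to the readout window
    for cloud in clouds:
        _relax_cloud(cloud, t_window - tau)

    # Readout: the per-sample sequence "advance clock, re-localize,
    # precess under the frequency-encode step, relax over one dwell,
    # retire crossed particles, sample" is evaluated in closed form per
    # line — z-rotations commute with the isotropic T2 scaling, so each
    # particle's transverse component at sample p is its window-start
    # value times E2^p times the accumulated phase, gated by an alive
    # mask from sample p onward once it crosses the outlet.  Particles
    # injected mid-line carry no transverse magnetization and so would
    # contribute zero; they are instantiated at the next TR boundary.
    fovx = protocol.fov[0]
    x_c = protocol.fov_center[0]
    t_samples = t_tr + t_window + np.arange(nx) * dwell
    two_pi_fov = 2.0 * np.pi / fovx
    for cloud in clouds:
        if cloud.n_particles == 0:
            continue
        tis = cloud.tissue
        n = cloud.n_particles
        x0 = cloud.coord_at(np.float64(t_samples[0]), 0) - x_c
        x1 = cloud.coord_at(np.float64(t_samples[-1]), 0) - x_c
        m0 = cloud.M[:, 0] + 1j * cloud.M[:, 1]
        e2_step = np.exp(-dwell / tis.T2)
        shift_step = tis.chemical_shift * dwell
        mkT = np.empty((nx, n), dtype=complex)  # sample-major layout
        # x constant over the 2.5 ms window (true for every axial-flow
        # section; 1e-9 mm ~ 1e-9 rad of phase): the per-sample phase is
        # then linear in the sample index and a complex-multiply
        # recursion replaces the per-sample exponentials
        const = np.abs(x1 - x0) <= 1e-9
        var = ~const
        if const.all():
            cur = m0 * np.exp(1j * two_pi_fov * (nx // 2) * x0)
            ratio = e2_step * np.exp(1j * (shift_step - two_pi_fov * x0))
            for p in range(nx):
                mkT[p] = cur
                cur = cur * ratio
        else:
            if np.any(const):
                cidx = np.flatnonzero(const)
                xs = x0[cidx]
                cur = m0[cidx] * np.exp(1j * two_pi_fov * (nx // 2) * xs)
                ratio = e2_step * np.exp(1j * (shift_step - two_pi_fov * xs))
                for p in range(nx):
                    mkT[p, cidx] = cur
                    cur = cur * ratio
            if np.any(var):
                idx = np.flatnonzero(var)
                x = cloud.coord_at(t_samples, 0)[idx] - x_c  # (Nv, nx)
                phase = two_pi_fov * (
                    (nx // 2) * x[:, :1] - np.cumsum(x, axis=1) + x[:, :1]
                )
                if shift_step:
                    phase = phase + shift_step * np.arange(nx)
                decay = e2_step ** np.arange(nx)
                mkT[:, idx] = ((m0[idx, None] * decay) * np.exp(1j * phase)).T
        # particles crossing the outlet mid-window stop contributing
        # from that sample on (they are compacted at the next TR)
        if cloud.is_moving:
            transit = cloud.transit[cloud.traj]
            dying = t_samples[-1] - cloud.entry > transit + 1e-9
            if np.any(dying):
                d_idx = np.flatnonzero(dying)
                alive = (
                    t_samples[:, None] - cloud.entry[d_idx]
                    <= transit[d_idx] + 1e-9
                )
                mkT[:, d_idx] *= alive
        samples += mkT @ cloud.particle_volumes
        # advance stored state to the end of the window
        m_end = mkT[-1]
        cloud.M[:, 0] = m_end.real
        cloud.M[:, 1] = m_end.imag
        e1 = np.exp(-(nx - 1) * dwell / tis.T1)
        cloud.M[:, 2] = tis.proton_density + (cloud.M[:, 2] - tis.proton_density) * e1
    # relax to the end of TR, then spoil
    t_window_end = t_window + (nx - 1) * dwell
    for cloud in clouds:
        _relax_cloud(cloud, protocol.TR - t_window_end)
        cloud.M[:, 0] = 0.0
        cloud.M[:, 1] = 0.0
    return samples


def _relax_cloud(cloud, dt: float) -> None:
    if dt <= 0:
        return
    tis = cloud.tissue
    _relax_inplace(
        cloud.M, np.exp(-dt / tis.T1), np.exp(-dt / tis.T2), tis.proton_density
    )
    if tis.chemical_shift:
        _precess_inplace(cloud.M, tis.chemical_shift * dt)


def default_line_order(protocol: Protocol) -> List[Tuple[int, int]]:
    """Sequential ky within kz, kz ascending."""
    _, ny, nz = protocol.matrix
    return [
        (ky, kz)
        for kz in range(-(nz // 2), nz - nz // 2)
        for ky in range(-(ny // 2), ny - ny // 2)
    ]


def simulate_slab(
    components,
    protocol: Protocol,
    slab: Tuple[float, float],
    line_order: Optional[List[Tuple[int, int]]] = None,
    t_start: float = 0.0,
) -> KSpaceVolume:
    """Simulate the full k-space of one slab.

    ``components`` is a list of :class:`MovingComponent` /
    :class:`StationaryComponent`; fresh particle clouds are instantiated
    at ``t_start`` and their magnetization state is maintained
    continuously across all Ny*Nz TRs (plus optional dummy TRs).
    """
    nx, ny, nz = protocol.matrix
    clouds = [c.make_cloud(t0=t_start) for c in components]
    if line_order is None:
        line_order = default_line_order(protocol)
    if len(line_order) != ny * nz:
        raise ValueError("line order must cover exactly Ny * Nz lines")
    data = np.zeros((nx, ny, nz), dtype=complex)
    t = t_start
    for _ in range(protocol.dummy_trs):
        acquire_line(clouds, protocol, slab, 0, 0, t)
        t += protocol.TR
    for ky, kz in line_order:
        line = acquire_line(clouds, protocol, slab, ky, kz, t)
        data[:, ky + ny // 2, kz + nz // 2] = line
        t += protocol.TR
    return KSpaceVolume(
        data=data,
        fov=protocol.fov,
        slab=slab,
        meta={"n_lines": ny * nz, "t_start": t_start},
    )


def run_chunked(
    components,
    protocol: Protocol,
    slab: Tuple[float, float],
    n_chunks: int = 1,
    line_order: Optional[List[Tuple[int, int]]] = None,
) -> KSpaceVolume:
    """Simulate trajectory chunks independently and sum their k-spaces.

    Moving components are partitioned into ``n_chunks`` contiguous
    trajectory chunks simulated in isolation (stationary components form
    their own chunk); since the signal is a sum over particles the
    result equals the single-chunk simulation to floating-point
    accumulation order.
    """
    if n_chunks < 1:
        raise ValueError("n_chunks must be >= 1")
    partial: Optional[KSpaceVolume] = None
    for chunk in range(n_chunks):
        chunk_components = []
        for comp in components:
            if isinstance(comp, MovingComponent):
                idx = np.array_split(np.arange(comp.n_trajectories), n_chunks)[chunk]
                if idx.size == 0:
                    continue
                chunk_components.append(_subset_component(comp, idx))
            elif chunk == 0:
                chunk_components.append(comp)
        if not chunk_components:
            continue
        k = simulate_slab(chunk_components, protocol, slab, line_order=line_order)
        partial = k if partial is None else partial + k
    if partial is None:
        nx, ny, nz = protocol.matrix
        partial = KSpaceVolume(
            data=np.zeros((nx, ny, nz), dtype=complex),
            fov=protocol.fov, slab=slab,
        )
    return partial


def _subset_component(comp: MovingComponent, idx) -> MovingComponent:
    idx = list(idx)
    sub_bundle = TrajectoryBundle([comp.bundle.trajectories[i] for i in idx])
    sub_seed = [
        TrajectorySeeding(
            trajectory_id=k,
            inlet_area=comp.seedings[i].inlet_area,
            spacing=comp.seedings[i].spacing,
            injection_interval=comp.seedings[i].injection_interval,
            particle_volume=comp.seedings[i].particle_volume,
        )
        for k, i in enumerate(idx)
    ]
    return MovingComponent(
        bundle=sub_bundle, seedings=sub_seed, tissue=comp.tissue,
        flow_sign=comp.flow_sign,
    )
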