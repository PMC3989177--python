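"""Analytic laminar flow fields and particle-trajectory integration.

The velocity model is quasi-one-dimensional Poiseuille flow: at every
cross-section the axial profile is parabolic,

    v(r, s) = v_max(s) * (1 - (r / R(s))^2),    v_max(s) = 2 Q / (pi R(s)^2),

so the volumetric flux through every cross-section equals the prescribed
flow rate Q (continuity).  In a narrowing the radius R(s) varies and a
radial component derived from the incompressibility condition,

    v_r(r, s) = (2 Q / pi) * R'(s) * (r / R^3) * (1 - (r/R)^2),

keeps streamlines on surfaces of constant relative radius r/R(s).  Fluid
threads therefore accelerate through a stenosis throat in inverse
proportion to the local area and relax back downstream, without lateral
mixing.  Turbulent post-stenotic jets are deliberately not modeled.

Units: mm, ms, flow rate in mm^3/ms (1 ml/s = 1 mm^3/ms).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np

from .geometry import OutsideLumenError, TubeGeometry

__all__ = [
    "FlowField",
    "Trajectory",
    "TrajectoryBundle",
    "TrajectoryWindowError",
    "integrate_trajectory",
    "interpolate_position",
    "trace_bundle",
]


class TrajectoryWindowError(ValueError):
    """Raised when a time falls outside a trajectory's lifetime."""


@dataclass(frozen=True)
class FlowField:
    """Steady laminar velocity field inside one tube.

    ``direction`` +1 drives the fluid from s=0 toward s=length, -1 the
    reverse (used for counter-flow channels such as the return leg pairs
    in multi-channel phantoms).
    """

    geometry: TubeGeometry
    flow_rate: float  # mm^3/ms
    direction: int = 1

    def __post_init__(self) -> None:
        if self.flow_rate <= 0:
            raise ValueError("flow_rate must be positive")
        if self.direction not in (-1, 1):
            raise ValueError("direction must be +1 or -1")

    def v_max(self, s):
        """Centerline speed at arc position s [mm/ms]."""
        R = self.geometry.radius(s)
        return 2.0 * self.flow_rate / (np.pi * R**2)

    def velocity(self, points, check: bool = True):
        """Velocity vectors [mm/ms] at lab-frame points (N, 3)."""
        points = np.atleast_2d(np.asarray(points, dtype=float))
        g = self.geometry
        s, r, tan, rad = g.locate(points)
        R = np.asarray(g.radius(s))
        if check:
            bad = (s < -1e-9) | (s > g.length + 1e-9) | (r > R * (1.0 + 1e-9))
            if np.any(bad):
                raise OutsideLumenError(
                    f"{int(bad.sum())} point(s) outside the lumen"
                )
        eta2 = np.clip((r / R) ** 2, 0.0, 1.0)
        vmax = 2.0 * self.flow_rate / (np.pi * R**2)
        v_ax = vmax * (1.0 - eta2)
        out = self.direction * v_ax[:, None] * tan
        dR = np.asarray(g.radius_derivative(s))
        if np.any(dR != 0.0):
            v_r = (2.0 * self.flow_rate / np.pi) * dR * (np.sqrt(eta2) / R**2) * (1.0 - eta2)
            out = out + self.direction * v_r[:, None] * rad
        return out

    def inlet_anchor(self):
        """(anchor, u, v) frame of the inlet cross-section."""
        end = "start" if self.direction == 1 else "end"
        return self.geometry.inlet_frame(end)

    def inlet_speed(self, inlet_points) -> np.ndarray:
        """Axial speed at 2D inlet coordinates."""
        pts = self.inlet_to_lab(inlet_points)
        return np.linalg.norm(self.velocity(pts), axis=1)

    def inlet_to_lab(self, inlet_points) -> np.ndarray:
        ip = np.atleast_2d(np.asarray(inlet_points, dtype=float))
        anchor, u, v = self.inlet_anchor()
        return anchor + ip[:, :1] * u + ip[:, 1:2] * v


@dataclass
class Trajectory:
    """Time-stamped path of one fluid thread.

    ``positions`` holds uniformly spaced samples (``dt_flow`` apart) that
    lie strictly inside the tube; ``transit_time`` and ``exit_position``
    describe the interpolated outlet crossing terminating the path.
    """

    id: int
    dt_flow: float
    positions: np.ndarray  # (n, 3)
    speeds: np.ndarray  # (n,)
    inlet_point: np.ndarray  # (2,)
    transit_time: float
    exit_position: np.ndarray  # (3,)

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.positions.shape[0]) * self.dt_flow

    @property
    def n_samples(self) -> int:
        return self.positions.shape[0]


def integrate_trajectory(
    flow_field: FlowField,
    inlet_point,
    dt_flow: float,
    n_steps: Optional[int] = None,
    traj_id: int = 0,
) -> Trajectory:
    """Trace one particle path from the inlet with explicit midpoint (RK2).

    The integration stops when the path crosses the outlet plane; the
    crossing instant is located by linear interpolation of the arc-length
    coordinate and stored as ``transit_time``.  ``n_steps`` caps the
    number of samples (default: generous bound from the inlet speed).
    """
    if dt_flow <= 0:
        raise ValueError("dt_flow must be positive")
    ff = flow_field
    g = ff.geometry
    inlet_point = np.asarray(inlet_point, dtype=float)
    if np.hypot(*inlet_point) >= g.radius(0.0 if ff.direction == 1 else g.length):
        raise OutsideLumenError("inlet point outside the inlet disc")
    p = ff.inlet_to_lab(inlet_point[None, :])[0]
    v0 = ff.velocity(p[None, :])[0]
    speed0 = float(np.linalg.norm(v0))
    if n_steps is None:
        est = g.length / max(speed0, 1e-12) / dt_flow
        n_steps = int(min(max(est * 4, 16), 5_000_000))

    positions = [p.copy()]
    arc = _arc_progress(g, p[None, :], ff.direction)[0]
    transit_time = None
    exit_position = None
    for k in range(n_steps):
        v1 = ff.velocity(p[None, :], check=False)[0]
        mid = p + 0.5 * dt_flow * v1
        v2 = ff.velocity(mid[None, :], check=False)[0]
        p_next = p + dt_flow * v2
        arc_next = _arc_progress(g, p_next[None, :], ff.direction)[0]
        if arc_next >= g.length:
            f = (g.length - arc) / max(arc_next - arc, 1e-30)
            transit_time = (k + f) * dt_flow
            exit_position = p + f * (p_next - p)
            break
        p = p_next
        arc = arc_next
        positions.append(p.copy())
    if transit_time is None:
        # ran out of steps (very slow near-wall thread): truncate at last sample
        transit_time = (len(positions) - 1) * dt_flow
        exit_position = positions[-1].copy()
    positions = np.asarray(positions)
    # sample speeds are field magnitudes at the sample positions
    speeds = np.linalg.norm(ff.velocity(positions, check=False), axis=1)
    return Trajectory(
        id=traj_id,
        dt_flow=dt_flow,
        positions=positions,
        speeds=np.asarray(speeds),
        inlet_point=inlet_point,
        transit_time=float(transit_time),
        exit_position=np.asarray(exit_position),
    )


def _arc_progress(geometry: TubeGeometry, points, direction: int):
    """Arc length traveled from the inlet (monotone along a path)."""
    s, _, _, _ = geometry.locate(points)
    return s if direction == 1 else geometry.length - s


def interpolate_position(traj: Trajectory, t):
    """Position at time(s) ``t`` by linear interpolation of the samples.

    Raises :class:`TrajectoryWindowError` for times before injection
    (t < 0) or after the outlet crossing (t > transit_time).
    """
    t = np.asarray(t, dtype=float)
    scalar = t.ndim == 0
    tt = np.atleast_1d(t)
    if np.any(tt < -1e-12) or np.any(tt > traj.transit_time + 1e-12):
        raise TrajectoryWindowError(
            "time outside trajectory lifetime "
            f"[0, {traj.transit_time:.6g}] ms"
        )
    pos = _interp_samples(
        tt, traj.dt_flow, traj.positions, traj.transit_time, traj.exit_position
    )
    return pos[0] if scalar else pos


def _interp_samples(tt, dt, positions, transit_time, exit_position):
    n = positions.shape[0]
    pts = np.concatenate([positions, exit_position[None, :]], axis=0)
    times = np.concatenate([np.arange(n) * dt, [max(transit_time, (n - 1) * dt + 1e-30)]])
    tt = np.clip(tt, 0.0, transit_time)
    idx = np.minimum((tt / dt).astype(int), n - 1)
    t0 = times[idx]
    t1 = times[idx + 1]
    f = np.clip((tt - t0) / np.maximum(t1 - t0, 1e-30), 0.0, 1.0)
    return pts[idx] * (1.0 - f)[:, None] + pts[idx + 1] * f[:, None]


class TrajectoryBundle:
    """Columnar container for a tube's trajectory bundle.

    Stores all samples in one concatenated array for vectorized position
    lookup across particles living on different trajectories; this is the
    formal hand-off between the flow stage and the MR stage.
    """

    def __init__(self, trajectories: Sequence[Trajectory]):
        if not trajectories:
            raise ValueError("empty trajectory bundle")
        self.trajectories = list(trajectories)
        counts = np.array([t.n_samples for t in trajectories])
        self.offsets = np.concatenate([[0], np.cumsum(counts + 1)])  # +1: exit sample
        self.dt = np.array([t.dt_flow for t in trajectories])
        self.transit = np.array([t.transit_time for t in trajectories])
        self.n_samples = counts
        pts, times = [], []
        for t in trajectories:
            pts.append(t.positions)
            pts.append(t.exit_position[None, :])
            times.append(t.times)
            times.append([max(t.transit_time, (t.n_samples - 1) * t.dt_flow + 1e-30)])
        self.points = np.concatenate(pts, axis=0)
        self.sample_times = np.concatenate([np.concatenate(times)])
        self.inlet_speeds = np.array([t.speeds[0] for t in trajectories])
        self.inlet_points = np.array([t.inlet_point for t in trajectories])

    def __len__(self) -> int:
        return len(self.trajectories)

    def positions_at(self, traj_idx: np.ndarray, tau: np.ndarray) -> np.ndarray:
        """Vectorized position lookup; ``tau`` is clamped to each lifetime."""
        dt = self.dt[traj_idx]
        tau = np.clip(tau, 0.0, self.transit[traj_idx])
        local = np.minimum((tau / dt).astype(int), self.n_samples[traj_idx] - 1)
        g0 = self.offsets[traj_idx] + local
        t0 = self.sample_times[g0]
        t1 = self.sample_times[g0 + 1]
        f = np.clip((tau - t0) / np.maximum(t1 - t0, 1e-30), 0.0, 1.0)
        return self.points[g0] * (1.0 - f)[:, None] + self.points[g0 + 1] * f[:, None]

    def coord_at(self, traj_idx: np.ndarray, tau: np.ndarray, axis: int) -> np.ndarray:
        """Single-coordinate variant of :meth:`positions_at`.

        ``tau`` may be (N,) or (N, K) for batched lookup of K time points
        per particle (used by the readout inner loop).
        """
        tau = np.asarray(tau, dtype=float)
        batched = tau.ndim == 2
        if batched:
            dt = self.dt[traj_idx][:, None]
            transit = self.transit[traj_idx][:, None]
            nloc = (self.n_samples[traj_idx] - 1)[:, None]
            offs = self.offsets[traj_idx][:, None]
        else:
            dt = self.dt[traj_idx]
            transit = self.transit[traj_idx]
            nloc = self.n_samples[traj_idx] - 1
            offs = self.offsets[traj_idx]
        tau = np.clip(tau, 0.0, transit)
        local = np.minimum((tau / dt).astype(int), nloc)
        g0 = offs + local
        t0 = self.sample_times[g0]
        t1 = self.sample_times[g0 + 1]
        f = np.clip((tau - t0) / np.maximum(t1 - t0, 1e-30), 0.0, 1.0)
        c = self.points[:, axis]
        return c[g0] * (1.0 - f) + c[g0 + 1] * f

    def velocities_at(self, traj_idx: np.ndarray, tau: np.ndarray) -> np.ndarray:
        """Velocity by finite difference of the bracketing samples."""
        dt = self.dt[traj_idx]
        tau = np.clip(tau, 0.0, self.transit[traj_idx])
        local = np.minimum((tau / dt).astype(int), self.n_samples[traj_idx] - 1)
        g0 = self.offsets[traj_idx] + local
        span = np.maximum(self.sample_times[g0 + 1] - self.sample_times[g0], 1e-30)
        return (self.points[g0 + 1] - self.points[g0]) / span[:, None]


def trace_bundle(
    flow_field: FlowField,
    inlet_points,
    samples_per_trajectory: int = 1200,
    dt_flow: Optional[float] = None,
) -> TrajectoryBundle:
    """Integrate a whole bundle of trajectories from 2D inlet seeds.

    When ``dt_flow`` is not given, each trajectory gets its own step so
    that slow near-wall threads use proportionally longer steps and every
    path resolves to roughly ``samples_per_trajectory`` samples; linear
    interpolation between samples stays far below a voxel of error for
    these smooth paths.
    """
    inlet_points = np.atleast_2d(np.asarray(inlet_points, dtype=float))
    n = inlet_points.shape[0]
    ff = flow_field
    g = ff.geometry
    speeds0 = ff.inlet_speed(inlet_points)
    if dt_flow is None:
        dt = g.length / np.maximum(speeds0, 1e-12) / samples_per_trajectory
    else:
        dt = np.full(n, float(dt_flow))

    p = ff.inlet_to_lab(inlet_points)
    pos_hist: List[List[np.ndarray]] = [[p[i].copy()] for i in range(n)]
    transit = np.full(n, np.nan)
    exit_pos = np.zeros((n, 3))
    arc = _arc_progress(g, p, ff.direction)
    active = np.ones(n, dtype=bool)
    max_steps = 4 * samples_per_trajectory if dt_flow is None else 5_000_000
    for k in range(max_steps):
        if not active.any():
            break
        idx = np.flatnonzero(active)
        pa = p[idx]
        da = dt[idx][:, None]
        v1 = ff.velocity(pa, check=False)
        v2 = ff.velocity(pa + 0.5 * da * v1, check=False)
        p_next = pa + da * v2
        arc_next = _arc_progress(g, p_next, ff.direction)
        crossed = arc_next >= g.length
        if np.any(crossed):
            ci = idx[crossed]
            f = (g.length - arc[ci]) / np.maximum(arc_next[crossed] - arc[ci], 1e-30)
            transit[ci] = (k + f) * dt[ci]
            exit_pos[ci] = pa[crossed] + f[:, None] * (p_next[crossed] - pa[crossed])
            active[ci] = False
        keep = ~crossed
        ki = idx[keep]
        p[ki] = p_next[keep]
        arc[ki] = arc_next[keep]
        for i in ki:
            pos_hist[i].append(p[i].copy())
    still = np.flatnonzero(active)
    if still.size:  # out of steps: truncate at the last sample
        for i in still:
            transit[i] = (len(pos_hist[i]) - 1) * dt[i]
            exit_pos[i] = pos_hist[i][-1]
    # sample speeds = field magnitudes at the sample positions (one
    # concatenated evaluation for the whole bundle)
    counts = [len(h) for h in pos_hist]
    all_pos = np.concatenate([np.asarray(h) for h in pos_hist], axis=0)
    all_speeds = np.linalg.norm(ff.velocity(all_pos, check=False), axis=1)
    bounds = np.concatenate([[0], np.cumsum(counts)])
    trajs = [
        Trajectory(
            id=i,
            dt_flow=float(dt[i]),
            positions=np.asarray(pos_hist[i]),
            speeds=all_speeds[bounds[i]:bounds[i + 1]],
            inlet_point=inlet_points[i],
            transit_time=float(transit[i]),
            exit_position=np.asarray(exit_pos[i]),
        )
        for i in range(n)
    ]
    return TrajectoryBundle(trajs)
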