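"""3D time-of-flight SPGR protocol definition and per-TR event scheduling.

A :class:`Protocol` fully describes the imaging experiment: timing
(TE/TR, readout window), flip angle with optional TONE ramp, matrix and
FOV, the MOTSA slab geometry, spatial presaturation and per-axis flow
compensation.  :func:`tr_schedule` expands one repetition into a
deterministic, time-ordered event list — presaturation, RF excitation,
phase encoding, free relaxation to the readout window, the sampling
comb with its gradient-echo center at TE, relaxation to the end of TR
and final spoiling — which the acquisition engine executes for every
(ky, kz) line: one k-space line per TR.

Angles are radians, times ms, lengths mm, gradient amplitudes mT/m.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .bloch import GAMMA

def _py(v):
    """Plain-Python scalar for YAML/JSON serialization."""
    if isinstance(v, (np.floating,)):
        return float(v)
    if isinstance(v, (np.integer,)):
        return int(v)
    if isinstance(v, (np.bool_,)):
        return bool(v)
    return v


__all__ = [
    "Protocol",
    "SlabPlan",
    "GradientEvent",
    "SequenceEvent",
    "plan_slabs",
    "phase_encode_offsets",
    "flow_comp_waveform",
    "bipolar_prephaser",
    "gradient_moments",
    "velocity_phase",
    "presaturate",
    "tr_schedule",
]


@dataclass
class Protocol:
    """Full ToF sequence description."""

    TE: float  # ms
    TR: float  # ms
    flip: float  # rad, nominal flip angle at the slab center
    matrix: Tuple[int, int, int]  # (Nx, Ny, Nz_per_slab)
    fov: Tuple[float, float, float]  # mm
    fov_center: Tuple[float, float] = (0.0, 0.0)  # in-plane FOV center, mm
    slab_width: float = 44.0  # mm
    slab_overlap: float = 0.0  # mm
    slice_thickness: float = 1.0  # mm
    readout_window: float = 2.56  # ms
    tone_enabled: bool = False
    tone_span: float = 0.0  # rad, total ramp over the slab
    presat_enabled: bool = False
    presat_side: str = "above"  # band placed above (+z) or below the slab
    presat_width: float = 40.0  # mm
    presat_gap: float = 5.0  # mm
    flow_comp: Tuple[bool, bool, bool] = (True, True, True)
    B0: float = 1.5  # T
    recon_matrix: Tuple[int, int] = (256, 256)
    rf_duration: float = 1.0  # ms
    rf_substeps_moving: int = 8
    rf_substeps_stationary: int = 1
    dummy_trs: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.TE < self.TR):
            raise ValueError("require 0 < TE < TR")
        nx, ny, nz = self.matrix
        if min(nx, ny, nz) < 1:
            raise ValueError("matrix dimensions must be positive")
        if self.slab_overlap >= self.slab_width:
            raise ValueError("slab_overlap must be smaller than slab_width")
        if abs(self.slice_thickness * nz - self.slab_width) > 1e-6:
            raise ValueError("slice_thickness * Nz_per_slab must equal slab_width")
        if self.readout_window <= 0:
            raise ValueError("readout_window must be positive")
        if self.presat_side not in ("above", "below"):
            raise ValueError("presat_side must be 'above' or 'below'")

    @property
    def dwell(self) -> float:
        """MRA clock step: readout window / Nx (Nyquist-matched)."""
        return self.readout_window / self.matrix[0]

    def to_dict(self) -> dict:
        d = asdict(self)
        for k in ("matrix", "fov", "fov_center", "flow_comp", "recon_matrix"):
            d[k] = [_py(v) for v in d[k]]
        return {k: (_py(v) if not isinstance(v, list) else v) for k, v in d.items()}

    @classmethod
    def from_dict(cls, d: dict) -> "Protocol":
        d = dict(d)
        for k in ("matrix", "fov", "fov_center", "flow_comp", "recon_matrix"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)


@dataclass(frozen=True)
class SlabPlan:
    """MOTSA slab stack: consecutive slabs overlap by exactly ``overlap``."""

    slabs: Tuple[Tuple[float, float], ...]  # (z_min, z_max) per slab
    overlap: float

    def __len__(self) -> int:
        return len(self.slabs)


def plan_slabs(fov_z: float, slab_width: float, overlap: float, z0: float = 0.0) -> SlabPlan:
    """Minimal stack of overlapping slabs covering [z0, z0 + fov_z]."""
    if overlap >= slab_width:
        raise ValueError("overlap must be smaller than slab_width")
    if overlap < 0:
        raise ValueError("overlap must be non-negative")
    if fov_z <= slab_width:
        return SlabPlan(slabs=((z0, z0 + slab_width),), overlap=overlap)
    step = slab_width - overlap
    n = int(np.ceil((fov_z - slab_width) / step)) + 1
    slabs = tuple(
        (z0 + i * step, z0 + i * step + slab_width) for i in range(n)
    )
    return SlabPlan(slabs=slabs, overlap=overlap)


def phase_encode_offsets(protocol: Protocol, ky: int, kz: int, position) -> np.ndarray:
    """Instantaneous phase [rad] imparted by the (ky, kz) encode step.

    ``position`` is (N, 3) in slab-local coordinates: y relative to the
    FOV center, z relative to the slab center.  Indices run over
    [-N/2, N/2).  The sign convention makes the acquired array a forward
    DFT of the object, so reconstruction is an inverse FFT.
    """
    nx, ny, nz = protocol.matrix
    if not (-ny // 2 <= ky < ny - ny // 2):
        raise IndexError(f"ky={ky} outside [-{ny//2}, {ny - ny//2})")
    if not (-nz // 2 <= kz < nz - nz // 2):
        raise IndexError(f"kz={kz} outside [-{nz//2}, {nz - nz//2})")
    p = np.atleast_2d(np.asarray(position, dtype=float))
    return -2.0 * np.pi * (
        ky * p[:, 1] / protocol.fov[1] + kz * p[:, 2] / protocol.slab_width
    )


# ---------------------------------------------------------------------------
# gradient lobes and flow compensation


@dataclass(frozen=True)
class GradientEvent:
    """Piecewise-constant gradient lobes on one axis.

    ``lobes`` is a sequence of (amplitude mT/m, duration ms) played
    back-to-back from ``start`` ms.
    """

    axis: str
    lobes: Tuple[Tuple[float, float], ...]
    start: float

    def __post_init__(self) -> None:
        if any(d <= 0 for _, d in self.lobes):
            raise ValueError("lobe durations must be positive")

    @property
    def end(self) -> float:
        return self.start + sum(d for _, d in self.lobes)

    def intervals(self):
        t = self.start
        for g, d in self.lobes:
            yield g, t, t + d
            t += d


def gradient_moments(events: Sequence[GradientEvent], t_ref: float, t_end: float):
    """Zeroth and first moments (about ``t_ref``) accumulated up to ``t_end``.

    m0 = integral G dt  [mT/m * ms];  m1 = integral G (t - t_ref) dt
    [mT/m * ms^2].  The phase of a spin at x(t) = x0 + v (t - t_ref) is
    gamma * 1e-6 * (m0 x0 + m1 v) rad (1e-6 converts mT/m*mm*ms to T*ms).
    """
    m0 = m1 = 0.0
    for ev in events:
        for g, a, b in ev.intervals():
            b = min(b, t_end)
            if b <= a:
                continue
            m0 += g * (b - a)
            m1 += g * ((b - t_ref) ** 2 - (a - t_ref) ** 2) / 2.0
    return m0, m1


def velocity_phase(
    events: Sequence[GradientEvent],
    x0: float,
    v: float,
    t_ref: float,
    t_end: float,
    n_quad: int = 20001,
) -> float:
    """Numerically integrated phase [rad] of a constant-velocity spin.

    Independent midpoint-rule check of the analytic moment formulas.
    """
    phase = 0.0
    for ev in events:
        for amp, a, b in ev.intervals():
            b = min(b, t_end)
            if b <= a:
                continue
            # midpoint rule per constant-amplitude piece (exact for the
            # linear spin position x0 + v*(t - t_ref))
            t = np.linspace(a, b, n_quad + 1)
            tm = 0.5 * (t[:-1] + t[1:])
            x = x0 + v * (tm - t_ref)
            phase += amp * np.sum(x) * (b - a) / n_quad
    return float(GAMMA * 1e-6 * phase)


def bipolar_prephaser(readout: GradientEvent, echo_time: float) -> GradientEvent:
    """Uncompensated prephaser: one lobe nulling only the zeroth moment.

    The lobe has the readout lobe's duration-to-echo and opposite area;
    a constant-velocity spin keeps a residual phase proportional to v.
    """
    (g_ro, _), = readout.lobes[:1]
    area = g_ro * (echo_time - readout.start)
    dur = echo_time - readout.start
    start = readout.start - dur
    if start < 0:
        raise ValueError("prephaser does not fit before the readout")
    return GradientEvent(axis=readout.axis, lobes=((-area / dur, dur),), start=start)


def flow_comp_waveform(readout: GradientEvent, echo_time: float) -> GradientEvent:
    """First-moment-nulled (velocity-compensated) readout prephaser.

    Replaces the bipolar prephaser by two equal-duration lobes whose
    amplitudes solve the 2x2 linear system: total zeroth moment at the
    echo center matches the base scheme (zero, so static spins refocus)
    and total first moment about the echo vanishes, cancelling the phase
    of constant-velocity spins.
    """
    dur = echo_time - readout.start
    start = readout.start - 2.0 * dur
    if start < 0:
        raise ValueError("flow compensation lobes exceed the available time before TE")
    m0_ro, m1_ro = gradient_moments([readout], echo_time, echo_time)
    # lobe 1 on [start, start+dur], lobe 2 on [start+dur, readout.start]
    a1, b1 = start, start + dur
    a2, b2 = start + dur, readout.start
    A = np.array(
        [
            [b1 - a1, b2 - a2],
            [((b1 - echo_time) ** 2 - (a1 - echo_time) ** 2) / 2.0,
             ((b2 - echo_time) ** 2 - (a2 - echo_time) ** 2) / 2.0],
        ]
    )
    rhs = np.array([-m0_ro, -m1_ro])
    g1, g2 = np.linalg.solve(A, rhs)
    return GradientEvent(axis=readout.axis, lobes=((g1, dur), (g2, dur)), start=start)


# ---------------------------------------------------------------------------
# presaturation


def presaturate(clouds, band: Tuple[float, float], t: float) -> None:
    """Saturate every particle inside the z band at time ``t``.

    Models one 90-degree pulse followed by ideal spoiling per TR:
    magnetization of in-band particles is zeroed; their longitudinal
    component then recovers with T1 as they travel toward the slab, so
    slow near-wall spins re-enter with partially recovered signal.
    """
    z_lo, z_hi = band
    if z_hi <= z_lo:
        raise ValueError("empty presaturation band")
    if not isinstance(clouds, (list, tuple)):
        clouds = [clouds]
    for cloud in clouds:
        if hasattr(cloud, "coord_at"):
            z = cloud.coord_at(np.float64(t), 2)
        else:
            z = cloud.positions_at(t)[:, 2]
        hit = (z >= z_lo) & (z <= z_hi)
        if np.any(hit):
            cloud.M[hit] = 0.0


def presat_band(protocol: Protocol, slab: Tuple[float, float]) -> Tuple[float, float]:
    """z interval of the presaturation band for the given slab."""
    if protocol.presat_side == "above":
        lo = slab[1] + protocol.presat_gap
        return (lo, lo + protocol.presat_width)
    hi = slab[0] - protocol.presat_gap
    return (hi - protocol.presat_width, hi)


# ---------------------------------------------------------------------------
# per-TR schedule


@dataclass(frozen=True)
class SequenceEvent:
    kind: str
    t: float  # start time within the TR, ms
    params: dict = field(default_factory=dict)


def tr_schedule(
    protocol: Protocol,
    slab: Tuple[float, float],
    ky: int,
    kz: int,
) -> List[SequenceEvent]:
    """Deterministic event list of one TR for phase-encode line (ky, kz).

    The echo center falls at ``rf_duration/2 + TE``; readout samples are
    spaced by ``protocol.dwell`` with the DC sample (kx = 0) exactly at
    the echo.  Raises if the scheduled events do not fit inside TE/TR.
    """
    nx, ny, nz = protocol.matrix
    if not (-ny // 2 <= ky < ny - ny // 2) or not (-nz // 2 <= kz < nz - nz // 2):
        raise IndexError("phase-encode index out of range")
    tau = protocol.rf_duration
    dwell = protocol.dwell
    echo = tau / 2.0 + protocol.TE
    t_window = echo - (nx // 2) * dwell
    if t_window < tau:
        raise ValueError(
            "TE too short: readout window would overlap the RF pulse"
        )
    t_window_end = t_window + (nx - 1) * dwell
    if t_window_end >= protocol.TR:
        raise ValueError("readout window exceeds TR")
    events: List[SequenceEvent] = []
    if protocol.presat_enabled:
        events.append(SequenceEvent("presat", 0.0, {"band": presat_band(protocol, slab)}))
    events.append(
        SequenceEvent(
            "rf", 0.0,
            {"flip": protocol.flip, "duration": tau,
             "tone": protocol.tone_enabled, "tone_span": protocol.tone_span},
        )
    )
    events.append(SequenceEvent("phase_encode", tau, {"ky": ky, "kz": kz}))
    events.append(SequenceEvent("relax", tau, {"until": t_window}))
    events.append(
        SequenceEvent(
            "readout", t_window,
            {"n_samples": nx, "dwell": dwell, "echo": echo},
        )
    )
    events.append(SequenceEvent("relax", t_window_end, {"until": protocol.TR}))
    events.append(SequenceEvent("spoil", protocol.TR, {}))
    return events
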