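"""Discrete-time analytic Bloch evolution of spin magnetization.

All operators act on magnetization arrays of shape (N, 3) (or (3,)) and
implement the standard piecewise-constant-field analytic solution:

* free precession — rotation of the transverse plane about z,
* relaxation — exponential T2 decay of (Mx, My) and T1 recovery of Mz
  toward the equilibrium value M0 = rho,
* RF excitation — rotation about the effective field axis, which tilts
  away from the transverse plane under off-resonance; pulses are
  subdivided so moving spins can enter/leave the excited slab mid-pulse,
* ideal spoiling — transverse magnetization zeroed at the end of a TR.

Rotation convention: RF phase 0 places the effective-field azimuth along
+x and a positive on-resonance flip rotates +z toward -y; any
self-consistent convention yields identical magnitude images.

Units: ms, rad, rad/ms.  The gyromagnetic ratio for protons is
``GAMMA`` = 2*pi*42.577e3 rad/(ms*T).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Tuple

import numpy as np

from .seeding import TissueProperties

__all__ = [
    "GAMMA",
    "RFPulse",
    "relax",
    "precess",
    "effective_flip",
    "rf_excite",
    "tone_flip",
    "spoil",
    "ernst_signal",
]

GAMMA = 2.0 * np.pi * 42.577e3  # rad / (ms * T), protons


@dataclass(frozen=True)
class RFPulse:
    """A rectangular RF pulse.

    ``flip`` is the nominal on-resonance flip angle [rad], ``phase`` the
    RF phase [rad], ``duration`` the pulse width [ms] and ``n_substeps``
    how many sub-rotations the pulse is divided into so that moving
    spins are re-localized mid-pulse (spins outside the slab profile at
    a substep receive no rotation for it).
    """

    flip: float
    phase: float = 0.0
    duration: float = 1.0
    n_substeps: int = 1

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("pulse duration must be positive")
        if self.n_substeps < 1:
            raise ValueError("n_substeps must be >= 1")


def relax(M, dt: float, tissue: TissueProperties):
    """Relaxation over ``dt`` ms: T2 decay + T1 recovery toward (0,0,rho)."""
    if dt < 0:
        raise ValueError("dt must be non-negative")
    if tissue.T1 <= 0 or tissue.T2 <= 0:
        raise ValueError("relaxation times must be positive")
    M = np.array(M, dtype=float, copy=True)
    e1 = np.exp(-dt / tissue.T1)
    e2 = np.exp(-dt / tissue.T2)
    M0 = tissue.proton_density
    M[..., 0] *= e2
    M[..., 1] *= e2
    M[..., 2] = M0 + (M[..., 2] - M0) * e1
    return M


def precess(M, angle):
    """Rotate (Mx, My) about z by ``angle`` [rad]; Mz is untouched.

    ``angle`` may be a scalar or a per-spin array; pass
    ``total_offset * dt`` for free precession under a frequency offset.
    """
    M = np.array(M, dtype=float, copy=True)
    angle = np.asarray(angle, dtype=float)
    c, s = np.cos(angle), np.sin(angle)
    mx = M[..., 0] * c - M[..., 1] * s
    my = M[..., 0] * s + M[..., 1] * c
    M[..., 0] = mx
    M[..., 1] = my
    return M


def effective_flip(alpha, tau: float, delta_omega):
    """Effective flip angle and effective-field tilt under off-resonance.

    With the nominal on-resonance rotation rate ``omega1 = alpha / tau``
    and frequency offset ``delta_omega`` [rad/ms]:

        alpha_eff = tau * sqrt(omega1**2 + delta_omega**2)
        theta     = atan2(omega1, delta_omega)

    ``theta`` is the angle of the effective field from +z: pi/2 exactly
    on resonance, -> 0 for very large offsets (no excitation).
    """
    if tau <= 0:
        raise ValueError("pulse duration must be positive")
    alpha = np.asarray(alpha, dtype=float)
    delta_omega = np.asarray(delta_omega, dtype=float)
    omega1 = alpha / tau
    alpha_eff = tau * np.hypot(omega1, delta_omega)
    theta = np.arctan2(omega1, delta_omega)
    return alpha_eff, theta


def _rotate_about_axis(M, axis, angle):
    """Rodrigues rotation of (N,3) vectors about per-row unit axes."""
    c = np.cos(angle)[..., None]
    s = np.sin(angle)[..., None]
    k = axis
    kdotm = np.sum(k * M, axis=-1, keepdims=True)
    return M * c + np.cross(k, M) * s + k * kdotm * (1.0 - c)


def rf_excite(
    M,
    pulse: RFPulse,
    delta_omega=0.0,
    position_provider: Optional[Callable[[float], np.ndarray]] = None,
    in_profile: Optional[Callable[[np.ndarray], np.ndarray]] = None,
    flip_of_position: Optional[Callable[[np.ndarray], np.ndarray]] = None,
    t_start: float = 0.0,
):
    """Apply one RF pulse, subdivided so spins can move mid-pulse.

    Parameters
    ----------
    M : (N, 3) array
    pulse : RFPulse
    delta_omega : scalar or (N,) array
        Off-resonance offset [rad/ms] during the pulse.
    position_provider : callable t -> (N, 3), optional
        Re-localizes spins at each substep midpoint.  Stationary spins
        may omit it (positions assumed constant).
    in_profile : callable positions -> bool mask, optional
        Ideal rectangular slab profile: spins outside receive no
        rotation for that substep, so a spin that exits the slab halfway
        through the pulse accumulates only about half the flip.
    flip_of_position : callable positions -> (N,) flip angles, optional
        Spatially varying nominal flip (TONE ramp).  Defaults to the
        pulse's nominal flip everywhere.
    t_start : float
        Absolute time of the pulse start, forwarded to the providers.
    """
    M = np.atleast_2d(np.array(M, dtype=float, copy=True))
    n = M.shape[0]
    sub = pulse.n_substeps
    tau_sub = pulse.duration / sub
    for k in range(sub):
        t_mid = t_start + (k + 0.5) * tau_sub
        if position_provider is not None:
            pos = np.atleast_2d(position_provider(t_mid))
        else:
            pos = None
        if flip_of_position is not None and pos is not None:
            alpha = np.asarray(flip_of_position(pos), dtype=float)
        else:
            alpha = np.full(n, pulse.flip)
        alpha_eff, theta = effective_flip(alpha / sub, tau_sub, delta_omega)
        alpha_eff = np.broadcast_to(alpha_eff, (n,)).copy()
        theta = np.broadcast_to(theta, (n,))
        if in_profile is not None and pos is not None:
            mask = np.asarray(in_profile(pos), dtype=bool)
            alpha_eff = np.where(mask, alpha_eff, 0.0)
        on_resonance = np.ndim(delta_omega) == 0 and float(delta_omega) == 0.0
        if on_resonance and pulse.phase == 0.0:
            # effective field along +x: right-hand rotation by +alpha
            # takes +z to -y without the general Rodrigues machinery
            c = np.cos(alpha_eff)
            s = np.sin(alpha_eff)
            my = M[:, 1] * c - M[:, 2] * s
            M[:, 2] = M[:, 2] * c + M[:, 1] * s
            M[:, 1] = my
        else:
            axis = np.stack(
                [
                    np.sin(theta) * np.cos(pulse.phase) * np.ones(n),
                    np.sin(theta) * np.sin(pulse.phase) * np.ones(n),
                    np.cos(theta) * np.ones(n),
                ],
                axis=-1,
            )
            # right-hand rotation about +x by +alpha takes +z to -y
            M = _rotate_about_axis(M, axis, alpha_eff)
    return M


def tone_flip(
    alpha_nominal: float,
    z,
    slab: Tuple[float, float],
    span: float,
    flow_direction: int = 1,
):
    """Linear TONE flip-angle ramp across a slab.

    The nominal angle applies at the slab center; the ramp spans
    ``span`` radians over the full slab width, increasing along the flow
    direction so that entering spins see ``alpha - span/2`` and exiting
    spins ``alpha + span/2``.
    """
    z = np.asarray(z, dtype=float)
    z_min, z_max = slab
    if np.any(z < z_min - 1e-9) or np.any(z > z_max + 1e-9):
        raise ValueError("z outside slab")
    z_c = 0.5 * (z_min + z_max)
    return alpha_nominal + span * ((z - z_c) / (z_max - z_min)) * flow_direction


def spoil(M):
    """Ideal spoiling: transverse magnetization destroyed, Mz kept."""
    M = np.array(M, dtype=float, copy=True)
    M[..., 0] = 0.0
    M[..., 1] = 0.0
    return M


def ernst_signal(alpha: float, TR: float, T1: float, M0: float = 1.0) -> float:
    """Closed-form spoiled steady-state transverse signal just after the pulse,

        M0 * sin(alpha) * (1 - E1) / (1 - E1 * cos(alpha)),  E1 = exp(-TR/T1).

    Used as the analytic oracle for the SPGR saturation level.
    """
    e1 = np.exp(-TR / T1)
    return M0 * np.sin(alpha) * (1.0 - e1) / (1.0 - e1 * np.cos(alpha))
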