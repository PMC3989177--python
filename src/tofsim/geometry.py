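"""Parametric vessel geometries for digital flow phantoms.

Three tube kinds are supported, mirroring the channels of commercial
calibration flow phantoms:

* ``straight`` — a circular cylinder of constant radius,
* ``stenosed`` — a cylinder with a cosine-tapered concentric narrowing,
* ``ubend``   — two vertical legs joined by a semicircular arc.

Lengths are millimetres throughout; straight-tube axes run along +z
(the direction of the main magnetic field B0).  A geometry exposes its
centerline as a function of arc length ``s`` together with the local
lumen radius ``R(s)``, which is all the laminar flow model needs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Tuple

import numpy as np

__all__ = [
    "TubeGeometry",
    "GeometryError",
    "OutsideLumenError",
    "make_geometry",
]


class GeometryError(ValueError):
    """Raised for unsupported kinds or non-physical dimensions."""


class OutsideLumenError(ValueError):
    """Raised when a point lies outside the vessel lumen."""


@dataclass(frozen=True)
class TubeGeometry:
    """A single vessel channel with an analytic centerline.

    Parameters
    ----------
    kind : {"straight", "stenosed", "ubend"}
    diameter : float
        Unobstructed lumen diameter [mm].
    length : float
        Total centerline arc length [mm].
    stenosis_fraction : float
        Fraction of the *diameter* removed at the throat; a 50 % stenosis
        halves the diameter and therefore quarters the lumen area.
    stenosis_center, stenosis_extent : float
        Center position and axial extent of the cosine-tapered neck [mm].
    bend_radius : float
        Curvature radius of the U-bend arc [mm] (``ubend`` only).
    origin : tuple of float
        Displacement of the channel inlet in the lab frame [mm].
    """

    kind: str
    diameter: float
    length: float
    stenosis_fraction: float = 0.0
    stenosis_center: float = 0.0
    stenosis_extent: float = 10.0
    bend_radius: float = 0.0
    leg_length: float = 0.0
    origin: Tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if self.kind not in ("straight", "stenosed", "ubend"):
            raise GeometryError(f"unsupported geometry kind {self.kind!r}")
        if self.diameter <= 0:
            raise GeometryError("diameter must be positive")
        if self.length <= 0:
            raise GeometryError("length must be positive")
        if self.kind == "stenosed":
            f = self.stenosis_fraction
            if not (0.0 < f < 1.0):
                raise GeometryError(
                    "stenosis_fraction must lie in (0, 1); "
                    f"got {f} (f=1 closes the lumen)"
                )
            if self.stenosis_extent <= 0:
                raise GeometryError("stenosis_extent must be positive")
            lo = self.stenosis_center - self.stenosis_extent / 2.0
            hi = self.stenosis_center + self.stenosis_extent / 2.0
            if lo < 0.0 or hi > self.length:
                raise GeometryError("stenosis interval must lie inside [0, length]")
        if self.kind == "ubend":
            if self.bend_radius <= self.diameter / 2.0:
                raise GeometryError("bend_radius must exceed the tube radius")

    # -- radius profile ----------------------------------------------------

    @property
    def radius_nominal(self) -> float:
        return self.diameter / 2.0

    @property
    def throat_radius(self) -> float:
        """Lumen radius at the stenosis throat (= nominal for other kinds)."""
        return self.radius_nominal * (1.0 - self.stenosis_fraction)

    def radius(self, s):
        """Local lumen radius R(s) [mm]; C1-continuous cosine taper."""
        s = np.asarray(s, dtype=float)
        R0 = self.radius_nominal
        if self.kind != "stenosed":
            return np.broadcast_to(np.float64(R0), s.shape).copy() if s.shape else np.float64(R0)
        Rt = self.throat_radius
        u = (s - self.stenosis_center) / self.stenosis_extent
        inside = np.abs(u) < 0.5
        # depth 1 at throat, 0 at the taper edges, zero slope at both
        depth = np.where(inside, 0.5 * (1.0 + np.cos(2.0 * np.pi * np.clip(u, -0.5, 0.5))), 0.0)
        return R0 - (R0 - Rt) * depth

    def radius_derivative(self, s):
        """dR/ds [dimensionless], analytic."""
        s = np.asarray(s, dtype=float)
        if self.kind != "stenosed":
            return np.zeros(s.shape) if s.shape else np.float64(0.0)
        R0, Rt = self.radius_nominal, self.throat_radius
        u = (s - self.stenosis_center) / self.stenosis_extent
        inside = np.abs(u) < 0.5
        d = np.where(
            inside,
            (R0 - Rt) * np.pi / self.stenosis_extent
            * np.sin(2.0 * np.pi * np.clip(u, -0.5, 0.5)),
            0.0,
        )
        return d

    # -- centerline --------------------------------------------------------

    def centerline(self, s):
        """Return (position, tangent) of the centerline at arc length ``s``."""
        s = np.atleast_1d(np.asarray(s, dtype=float))
        o = np.asarray(self.origin)
        if self.kind in ("straight", "stenosed"):
            pos = np.zeros(s.shape + (3,))
            pos[..., 2] = s
            tan = np.zeros_like(pos)
            tan[..., 2] = 1.0
            return pos + o, tan
        # ubend: leg1 up +z, semicircle in the x-z plane, leg2 down -z
        leg = self.leg_length
        Rb = self.bend_radius
        pos = np.zeros(s.shape + (3,))
        tan = np.zeros_like(pos)
        s1, s2 = leg, leg + np.pi * Rb
        in_leg1 = s <= s1
        in_arc = (s > s1) & (s <= s2)
        in_leg2 = s > s2
        pos[in_leg1, 2] = s[in_leg1]
        tan[in_leg1, 2] = 1.0
        phi = (s[in_arc] - s1) / Rb
        pos[in_arc, 0] = Rb * (1.0 - np.cos(phi))
        pos[in_arc, 2] = leg + Rb * np.sin(phi)
        tan[in_arc, 0] = np.sin(phi)
        tan[in_arc, 2] = np.cos(phi)
        pos[in_leg2, 0] = 2.0 * Rb
        pos[in_leg2, 2] = leg - (s[in_leg2] - s2)
        tan[in_leg2, 2] = -1.0
        return pos + o, tan

    def locate(self, points):
        """Map lab-frame points to local coordinates.

        Returns ``(s, r, tangent, radial_unit)`` where ``s`` is arc length of
        the nearest centerline point, ``r`` the perpendicular distance to it,
        ``tangent`` the local flow axis and ``radial_unit`` the outward unit
        vector from the centerline to the point (zero on the axis).
        """
        p = np.atleast_2d(np.asarray(points, dtype=float)) - np.asarray(self.origin)
        if self.kind in ("straight", "stenosed"):
            s = p[:, 2].copy()
            r = np.hypot(p[:, 0], p[:, 1])
            tan = np.zeros_like(p)
            tan[:, 2] = 1.0
            rad = np.zeros_like(p)
            nz = r > 0
            rad[nz, 0] = p[nz, 0] / r[nz]
            rad[nz, 1] = p[nz, 1] / r[nz]
            return s, r, tan, rad
        leg, Rb = self.leg_length, self.bend_radius
        s = np.empty(p.shape[0])
        r = np.empty(p.shape[0])
        tan = np.zeros_like(p)
        rad = np.zeros_like(p)
        # region split: points above the leg tops belong to the arc
        arc_zone = p[:, 2] > leg
        leg1 = ~arc_zone & (p[:, 0] < Rb)
        leg2 = ~arc_zone & ~leg1
        s[leg1] = p[leg1, 2]
        r[leg1] = np.hypot(p[leg1, 0], p[leg1, 1])
        tan[leg1, 2] = 1.0
        s[leg2] = leg + np.pi * Rb + (leg - p[leg2, 2])
        r[leg2] = np.hypot(p[leg2, 0] - 2.0 * Rb, p[leg2, 1])
        tan[leg2, 2] = -1.0
        if np.any(arc_zone):
            q = p[arc_zone]
            phi = np.arctan2(q[:, 2] - leg, -(q[:, 0] - Rb))
            s[arc_zone] = leg + Rb * phi
            c = np.stack(
                [Rb * (1.0 - np.cos(phi)), np.zeros_like(phi), leg + Rb * np.sin(phi)],
                axis=1,
            )
            d = q - c
            r[arc_zone] = np.linalg.norm(d, axis=1)
            tan[arc_zone, 0] = np.sin(phi)
            tan[arc_zone, 2] = np.cos(phi)
            nz = r[arc_zone] > 0
            ru = np.zeros_like(d)
            ru[nz] = d[nz] / r[arc_zone][nz, None]
            rad[arc_zone] = ru
        for mask, cx in ((leg1, 0.0), (leg2, 2.0 * Rb)):
            if np.any(mask):
                d = p[mask].copy()
                d[:, 0] -= cx
                d[:, 2] = 0.0
                nz = r[mask] > 0
                ru = np.zeros_like(d)
                ru[nz] = d[nz] / r[mask][nz, None]
                rad[mask] = ru
        return s, r, tan, rad

    def inlet_frame(self, end: str = "start"):
        """Orthonormal (u, v) spanning the cross-section at an end.

        ``end`` is ``"start"`` (s=0) or ``"end"`` (s=length).  Returns the
        3D anchor point plus the two in-plane unit vectors; 2D inlet seeds
        (a, b) map to ``anchor + a*u + b*v``.
        """
        s = 0.0 if end == "start" else self.length
        pos, tan = self.centerline(np.array([s]))
        t = tan[0]
        helper = np.array([1.0, 0.0, 0.0])
        if abs(np.dot(helper, t)) > 0.9:
            helper = np.array([0.0, 1.0, 0.0])
        u = np.cross(helper, t)
        u /= np.linalg.norm(u)
        v = np.cross(t, u)
        return pos[0], u, v

    def contains(self, points, tol: float = 0.0):
        """Boolean mask of points inside the lumen."""
        s, r, _, _ = self.locate(points)
        return (s >= -tol) & (s <= self.length + tol) & (r <= self.radius(s) + tol)

    def lumen_volume(self, n_quad: int = 4096) -> float:
        """Numerical volume of the lumen, pi * integral of R(s)^2 ds."""
        s = (np.arange(n_quad) + 0.5) * self.length / n_quad
        return float(np.pi * np.mean(self.radius(s) ** 2) * self.length)


def make_geometry(spec: dict) -> TubeGeometry:
    """Build a :class:`TubeGeometry` from a plain-dict phantom spec.

    The spec requires ``kind`` plus ``diameter`` and, per kind, ``length``
    (straight/stenosed) or ``bend_radius`` and optional ``leg_length``
    (ubend).  A 50 % (of diameter) stenosis yields a throat diameter of
    half the nominal one.
    """
    spec = dict(spec)
    kind = spec.pop("kind", None)
    if kind not in ("straight", "stenosed", "ubend"):
        raise GeometryError(f"unsupported geometry kind {kind!r}")
    diameter = float(spec.pop("diameter"))
    origin = tuple(spec.pop("origin", (0.0, 0.0, 0.0)))
    if kind == "ubend":
        bend_radius = float(spec.pop("bend_radius"))
        height = float(spec.pop("height", 207.0))
        leg = float(spec.pop("leg_length", height - bend_radius))
        if leg <= 0:
            raise GeometryError("ubend leg length must be positive")
        length = 2.0 * leg + np.pi * bend_radius
        if spec:
            raise GeometryError(f"unknown keys in geometry spec: {sorted(spec)}")
        return TubeGeometry(
            kind="ubend", diameter=diameter, length=length,
            bend_radius=bend_radius, leg_length=leg, origin=origin,
        )
    length = float(spec.pop("length"))
    if kind == "straight":
        if spec:
            raise GeometryError(f"unknown keys in geometry spec: {sorted(spec)}")
        return TubeGeometry(kind="straight", diameter=diameter, length=length,
                            origin=origin)
    fraction = float(spec.pop("stenosis_fraction"))
    center = float(spec.pop("stenosis_center", length / 2.0))
    extent = float(spec.pop("stenosis_extent", 10.0))
    if spec:
        raise GeometryError(f"unknown keys in geometry spec: {sorted(spec)}")
    return TubeGeometry(
        kind="stenosed", diameter=diameter, length=length,
        stenosis_fraction=fraction, stenosis_center=center,
        stenosis_extent=extent, origin=origin,
    )
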