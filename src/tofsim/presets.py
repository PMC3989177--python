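"""Bundled digital phantoms and imaging-protocol presets.

The presets reproduce a commercial MR flow-calibration setup: four
straight channels (three of 8 mm diameter — one with a 75 % and one
with a 50 % diameter stenosis — and one of 5 mm), plus a U-bend channel
of 8 mm diameter with a 44 mm curvature radius; all straight channels
are 207 mm long.  The fluid is a glycerol/water blood-mimicking fluid
(BMF) with T1 = 850 ms and T2 = 170 ms at 1.5 T.  Four studies pair
flow rates with acquisition parameters:

====== =========== ============ ================== =================
study  rate [ml/s]  TE/TR [ms]   flip      slabs    FOV x/y/z [cm]
====== =========== ============ ================== =================
1      2.5          4.7 / 40     20 deg    44/8     17.5/13.4/14.4
2      2.5          4.7 / 40     15 deg    44/8     17.5/13.4/14.4
3      4.6          4.6 / 27     15 deg    44/8     17.5/13.4/22.4
4      10           4.6 / 27     15 deg    25/5     17.5/13.4/24.5
====== =========== ============ ================== =================

In-plane sampling is 224 (frequency) x 160 (phase) with 1 mm slices,
reconstructed on a 256 x 256 grid.  A ``scale`` factor shrinks matrix
and trajectory counts for desk-scale runs while leaving the physics
(timing, flip angles, flow rates, geometry) untouched.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional

import numpy as np
import yaml

from .engine import MovingComponent, StationaryComponent
from .flow import FlowField, trace_bundle
from .geometry import make_geometry
from .seeding import (
    TissueProperties,
    make_stationary_tissue,
    seed_trajectories,
    sunflower_points,
    voronoi_inlet_areas,
)
from .sequence import Protocol

__all__ = [
    "BMF_METADATA",
    "StudyPreset",
    "make_bmf",
    "make_study",
    "make_phantom",
    "build_phantom_model",
]

#: Non-magnetic fluid properties carried as metadata (kg/m^3, mPa*s).
BMF_METADATA = {"density": 1020.0, "viscosity": 4.1}

#: Default seeding densities of the digital phantoms.
DEFAULT_TRAJECTORIES_PER_TUBE = 256
DEFAULT_PARTICLES_PER_MM = 3.0

_STUDY_TABLE = {
    1: dict(flow_rate=2.5, TE=4.7, TR=40.0, flip_deg=20.0,
            slab_width=44.0, slab_overlap=8.0, fov_cm=(17.5, 13.4, 14.4)),
    2: dict(flow_rate=2.5, TE=4.7, TR=40.0, flip_deg=15.0,
            slab_width=44.0, slab_overlap=8.0, fov_cm=(17.5, 13.4, 14.4)),
    3: dict(flow_rate=4.6, TE=4.6, TR=27.0, flip_deg=15.0,
            slab_width=44.0, slab_overlap=8.0, fov_cm=(17.5, 13.4, 22.4)),
    4: dict(flow_rate=10.0, TE=4.6, TR=27.0, flip_deg=15.0,
            slab_width=25.0, slab_overlap=5.0, fov_cm=(17.5, 13.4, 24.5)),
}


def make_bmf() -> TissueProperties:
    """Blood-mimicking fluid: rho = 1.00, T1 = 850 ms, T2 = 170 ms at 1.5 T."""
    return TissueProperties(T1=850.0, T2=170.0, proton_density=1.0, name="bmf")


@dataclass
class StudyPreset:
    """One study setup: phantom + fluid + flow rate + protocol + scale."""

    study_id: int
    phantom: dict
    fluid: TissueProperties
    flow_rate: float  # mm^3/ms per channel
    protocol: Protocol
    scale: float = 1.0
    trajectories_per_tube: int = DEFAULT_TRAJECTORIES_PER_TUBE
    particles_per_mm: float = DEFAULT_PARTICLES_PER_MM

    def to_dict(self) -> dict:
        return {
            "study_id": self.study_id,
            "phantom": self.phantom,
            "fluid": asdict(self.fluid),
            "flow_rate": self.flow_rate,
            "protocol": self.protocol.to_dict(),
            "scale": self.scale,
            "trajectories_per_tube": self.trajectories_per_tube,
            "particles_per_mm": self.particles_per_mm,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StudyPreset":
        return cls(
            study_id=d["study_id"],
            phantom=d["phantom"],
            fluid=TissueProperties(**d["fluid"]),
            flow_rate=d["flow_rate"],
            protocol=Protocol.from_dict(d["protocol"]),
            scale=d.get("scale", 1.0),
            trajectories_per_tube=d.get(
                "trajectories_per_tube", DEFAULT_TRAJECTORIES_PER_TUBE
            ),
            particles_per_mm=d.get("particles_per_mm", DEFAULT_PARTICLES_PER_MM),
        )

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "StudyPreset":
        return cls.from_dict(yaml.safe_load(text))


def make_study(study_id: int, scale: float = 1.0,
               phantom_name: str = "four_tube") -> StudyPreset:
    """Assemble a study preset, optionally at reduced scale.

    ``scale`` multiplies the acquisition matrix and the per-tube
    trajectory count (rounded); all physical parameters — timing, flip
    angle, TONE span, slab geometry, FOV, flow rate — stay at their
    full-scale values, and the MRA clock keeps dwell = window / Nx.
    """
    if study_id not in _STUDY_TABLE:
        raise ValueError(f"unknown study id {study_id}; choose 1-4")
    if not (0 < scale <= 1.0):
        raise ValueError("scale must be in (0, 1]")
    row = _STUDY_TABLE[study_id]
    nx = max(int(round(224 * scale)), 8)
    ny = max(int(round(160 * scale)), 8)
    nz = max(int(round(row["slab_width"] * scale)), 4)
    fov = tuple(10.0 * v for v in row["fov_cm"])
    protocol = Protocol(
        TE=row["TE"],
        TR=row["TR"],
        flip=np.deg2rad(row["flip_deg"]),
        matrix=(nx, ny, nz),
        fov=fov,
        slab_width=row["slab_width"],
        slab_overlap=row["slab_overlap"],
        slice_thickness=row["slab_width"] / nz,
        readout_window=2.56,
        tone_enabled=True,
        tone_span=np.deg2rad(20.0),
        presat_enabled=True,
        flow_comp=(True, True, True),
        B0=1.5,
        recon_matrix=(256, 256),
    )
    return StudyPreset(
        study_id=study_id,
        phantom=make_phantom(phantom_name),
        fluid=make_bmf(),
        flow_rate=row["flow_rate"],
        protocol=protocol,
        scale=scale,
        trajectories_per_tube=max(int(round(DEFAULT_TRAJECTORIES_PER_TUBE * scale)), 8),
        particles_per_mm=DEFAULT_PARTICLES_PER_MM,
    )


def make_phantom(name: str) -> dict:
    """Named phantom specs (channel geometries + per-channel flow signs).

    ``four_tube``: channels on 25 mm centers along x — a 75 % stenosis
    (8 mm), a plain 8 mm, a 50 % stenosis (8 mm) and a plain 5 mm tube,
    all 207 mm long.  ``ubend``: one 8 mm channel with a 44 mm bend.
    ``stenosis50``/``stenosis75``: the isolated stenosed tubes.
    """
    L = 207.0
    if name == "four_tube":
        channels = [
            {"geometry": {"kind": "stenosed", "diameter": 8.0, "length": L,
                          "stenosis_fraction": 0.75, "origin": [-37.5, 0.0, 0.0]},
             "flow_sign": 1},
            {"geometry": {"kind": "straight", "diameter": 8.0, "length": L,
                          "origin": [-12.5, 0.0, 0.0]},
             "flow_sign": 1},
            {"geometry": {"kind": "stenosed", "diameter": 8.0, "length": L,
                          "stenosis_fraction": 0.5, "origin": [12.5, 0.0, 0.0]},
             "flow_sign": 1},
            {"geometry": {"kind": "straight", "diameter": 5.0, "length": L,
                          "origin": [37.5, 0.0, 0.0]},
             "flow_sign": 1},
        ]
    elif name == "ubend":
        channels = [
            {"geometry": {"kind": "ubend", "diameter": 8.0, "bend_radius": 44.0,
                          "height": L, "origin": [-44.0, 0.0, 0.0]},
             "flow_sign": 1},
        ]
    elif name == "stenosis50":
        channels = [
            {"geometry": {"kind": "stenosed", "diameter": 8.0, "length": L,
                          "stenosis_fraction": 0.5, "origin": [0.0, 0.0, 0.0]},
             "flow_sign": 1},
        ]
    elif name == "stenosis75":
        channels = [
            {"geometry": {"kind": "stenosed", "diameter": 8.0, "length": L,
                          "stenosis_fraction": 0.75, "origin": [0.0, 0.0, 0.0]},
             "flow_sign": 1},
        ]
    else:
        raise ValueError(f"unknown phantom name {name!r}")
    return {"name": name, "channels": channels}


def build_phantom_model(
    phantom: dict,
    fluid: TissueProperties,
    flow_rate: float,
    n_trajectories: int = DEFAULT_TRAJECTORIES_PER_TUBE,
    particles_per_mm: float = DEFAULT_PARTICLES_PER_MM,
    stationary: Optional[dict] = None,
    seed: Optional[int] = None,
    samples_per_trajectory: int = 1200,
) -> List:
    """Turn a phantom spec into simulation-ready components.

    For every channel: build the geometry, lay out ``n_trajectories``
    inlet seeds in a low-discrepancy sunflower pattern, integrate the
    trajectory bundle through the analytic laminar field, tessellate the
    inlet by a Voronoi decomposition and attach per-trajectory particle
    volumes at ``particles_per_mm`` linear density.  ``stationary``
    optionally adds a surrounding tissue box, e.g. ``{"box_lo": ...,
    "box_hi": ..., "tissue": TissueProperties(...), "density": 20.0}``.
    """
    rng = np.random.default_rng(seed)
    components: List = []
    geometries = []
    for ch in phantom["channels"]:
        geom = make_geometry(ch["geometry"])
        geometries.append(geom)
        sign = int(ch.get("flow_sign", 1))
        direction = 1 if sign >= 0 else -1
        ff = FlowField(geometry=geom, flow_rate=float(ch.get("flow_rate", flow_rate)),
                       direction=direction)
        inlet_r = geom.radius(0.0 if direction == 1 else geom.length)
        seeds = sunflower_points(n_trajectories, float(inlet_r) * 0.995)
        bundle = trace_bundle(ff, seeds, samples_per_trajectory=samples_per_trajectory)
        areas = voronoi_inlet_areas(seeds, float(inlet_r))
        seedings = seed_trajectories(bundle, areas, particles_per_mm)
        flow_sign = direction  # straight channels run along +z; ubend returns
        components.append(
            MovingComponent(bundle=bundle, seedings=seedings, tissue=fluid,
                            flow_sign=flow_sign)
        )
    if stationary is not None:
        cloud = make_stationary_tissue(
            stationary["box_lo"], stationary["box_hi"],
            stationary["tissue"], stationary["density"],
            exclude_geometries=geometries, rng=rng,
        )
        components.append(
            StationaryComponent(
                positions=cloud.positions_at(0.0),
                tissue=stationary["tissue"],
                particle_volume=1.0 / stationary["density"],
            )
        )
    return components
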