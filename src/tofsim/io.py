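"""File formats: HDF5 k-space, NIfTI magnitude volumes, trajectory tables."""

from __future__ import annotations

from pathlib import Path
from typing import List, Sequence

import h5py
import nibabel as nib
import numpy as np
import pandas as pd

from .engine import KSpaceVolume
from .flow import TrajectoryBundle
from .recon import ImageVolume

__all__ = [
    "save_kspace",
    "load_kspace",
    "save_nifti",
    "load_nifti",
    "trajectories_to_frame",
    "particles_to_frame",
]


def save_kspace(path, volumes: Sequence[KSpaceVolume], meta: dict | None = None) -> None:
    """Write slab k-spaces to one HDF5 file (complex arrays + metadata)."""
    with h5py.File(path, "w") as f:
        if meta:
            for k, v in meta.items():
                f.attrs[k] = v
        for i, vol in enumerate(volumes):
            g = f.create_group(f"slab_{i:03d}")
            g.create_dataset("data", data=vol.data)
            g.attrs["fov"] = vol.fov
            g.attrs["slab"] = vol.slab
            for k, v in vol.meta.items():
                if isinstance(v, (int, float, str)):
                    g.attrs[k] = v


def load_kspace(path) -> List[KSpaceVolume]:
    out = []
    with h5py.File(path, "r") as f:
        for name in sorted(k for k in f.keys() if k.startswith("slab_")):
            g = f[name]
            out.append(
                KSpaceVolume(
                    data=g["data"][()],
                    fov=tuple(g.attrs["fov"]),
                    slab=tuple(g.attrs["slab"]),
                    meta={k: g.attrs[k] for k in g.attrs if k not in ("fov", "slab")},
                )
            )
    return out


def save_nifti(path, image: ImageVolume) -> None:
    nib.save(nib.Nifti1Image(image.voxels.astype(np.float32), image.affine()), str(path))


def load_nifti(path) -> ImageVolume:
    img = nib.load(str(path))
    zooms = img.header.get_zooms()[:3]
    return ImageVolume(
        voxels=np.asarray(img.dataobj, dtype=float),
        spacing=tuple(float(z) for z in zooms),
        origin=tuple(float(v) for v in img.affine[:3, 3]),
    )


def trajectories_to_frame(bundle: TrajectoryBundle) -> pd.DataFrame:
    """Columnar (id, t, x, y, z, speed) table — the flow->MR hand-off format."""
    rows = []
    for traj in bundle.trajectories:
        n = traj.n_samples
        rows.append(
            pd.DataFrame(
                {
                    "id": np.full(n, traj.id, dtype=int),
                    "t": traj.times,
                    "x": traj.positions[:, 0],
                    "y": traj.positions[:, 1],
                    "z": traj.positions[:, 2],
                    "speed": traj.speeds,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def particles_to_frame(cloud, t: float) -> pd.DataFrame:
    """Snapshot of a particle cloud (label, position, M, volume)."""
    pos = cloud.positions_at(t)
    return pd.DataFrame(
        {
            "label": cloud.labels,
            "t": np.full(cloud.n_particles, t),
            "x": pos[:, 0],
            "y": pos[:, 1],
            "z": pos[:, 2],
            "Mx": cloud.M[:, 0],
            "My": cloud.M[:, 1],
            "Mz": cloud.M[:, 2],
            "volume": cloud.particle_volumes,
        }
    )
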