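"""Raw k-space to magnitude images.

Reconstruction follows the conventional gradient-echo pipeline: an
optional separable low-pass window on the phase-encode axes (to tame
phase-mismapping ghosts from moving spins), zero padding to the target
matrix (Fourier/sinc interpolation), a centered inverse FFT with
magnitude output, and finally compositing of overlapping MOTSA slabs
into one volume.  Complex white Gaussian noise can be added to k-space,
which produces the Rician/Rayleigh statistics of magnitude MR images.

k-space arrays are indexed (kx, ky, kz) with DC at index N//2.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy.fft import fftshift, ifftn, ifftshift
from scipy.signal.windows import tukey

from .engine import KSpaceVolume
from .sequence import SlabPlan

__all__ = [
    "ImageVolume",
    "lowpass_filter",
    "zero_pad",
    "reconstruct_magnitude",
    "composite_motsa",
    "add_kspace_noise",
]


@dataclass
class ImageVolume:
    """Reconstructed magnitude image with voxel geometry."""

    voxels: np.ndarray  # non-negative magnitudes, (Nx, Ny, Nz)
    spacing: Tuple[float, float, float]  # mm
    origin: Tuple[float, float, float] = (0.0, 0.0, 0.0)
    meta: dict = field(default_factory=dict)

    @property
    def shape(self):
        return self.voxels.shape

    def affine(self) -> np.ndarray:
        a = np.diag(list(self.spacing) + [1.0])
        a[:3, 3] = self.origin
        return a


def lowpass_filter(k: KSpaceVolume, alpha: float = 0.5,
                   axes: Sequence[int] = (1, 2)) -> KSpaceVolume:
    """Separable Tukey window on the phase-encode axes; DC gain 1.

    ``alpha`` is the Tukey taper fraction (0 = all-pass boxcar).  The
    window is centered on DC (index N//2) and normalized to unity there.
    """
    if not (0.0 <= alpha <= 1.0):
        raise ValueError("Tukey alpha must be in [0, 1]")
    data = k.data.copy()
    for ax in axes:
        n = data.shape[ax]
        w = tukey(n, alpha=alpha, sym=True)
        w = w / w[n // 2]  # unit gain exactly at the DC index
        shape = [1, 1, 1]
        shape[ax] = n
        data *= w.reshape(shape)
    return KSpaceVolume(data=data, fov=k.fov, slab=k.slab, meta=dict(k.meta))


def zero_pad(k: KSpaceVolume, target: Tuple[int, ...]) -> KSpaceVolume:
    """Center the raw samples in a larger grid (Fourier interpolation).

    DC (index N//2) stays at the target grid's DC position; padding a
    224x160 acquisition to 256x256 preserves all original samples and
    fills the rest with zeros.
    """
    src = k.data.shape
    target = tuple(target) + src[len(target):]
    if any(t < s for t, s in zip(target, src)):
        raise ValueError(f"target {target} smaller than source {src}")
    out = np.zeros(target, dtype=k.data.dtype)
    starts = [t // 2 - s // 2 for t, s in zip(target, src)]
    sl = tuple(slice(st, st + s) for st, s in zip(starts, src))
    out[sl] = k.data
    return KSpaceVolume(data=out, fov=k.fov, slab=k.slab, meta=dict(k.meta))


def reconstruct_magnitude(k: KSpaceVolume) -> ImageVolume:
    """Centered inverse FFT of the slab k-space; voxel values are |.|."""
    if not np.all(np.isfinite(k.data)):
        raise ValueError("non-finite k-space samples")
    img = fftshift(ifftn(ifftshift(k.data)))
    shape = k.data.shape
    spacing = (
        k.fov[0] / shape[0],
        k.fov[1] / shape[1],
        (k.slab[1] - k.slab[0]) / shape[2],
    )
    return ImageVolume(
        voxels=np.abs(img),
        spacing=spacing,
        origin=(-k.fov[0] / 2.0, -k.fov[1] / 2.0, k.slab[0]),
        meta=dict(k.meta),
    )


def composite_motsa(slab_images: Sequence[ImageVolume], plan: SlabPlan,
                    mode: str = "discard") -> ImageVolume:
    """Merge overlapping slab images into one volume.

    ``discard`` (default) drops half the overlapping slices from each
    adjoining slab so every output slice comes from exactly one slab;
    ``max`` keeps the maximum intensity across contributing slabs.
    """
    if len(slab_images) != len(plan):
        raise ValueError("one image per planned slab required")
    if mode not in ("discard", "max"):
        raise ValueError("mode must be 'discard' or 'max'")
    first = slab_images[0]
    for im in slab_images[1:]:
        if im.shape[:2] != first.shape[:2]:
            raise ValueError("slab images must share in-plane matrices")
        if not np.allclose(im.spacing[:2], first.spacing[:2]):
            raise ValueError("slab images must share in-plane spacing")
    if len(slab_images) == 1:
        return first
    dz = first.spacing[2]
    z0 = plan.slabs[0][0]
    z1 = plan.slabs[-1][1]
    n_out = int(round((z1 - z0) / dz))
    out = np.zeros(first.shape[:2] + (n_out,))
    if mode == "max":
        for im, (lo, _) in zip(slab_images, plan.slabs):
            start = int(round((lo - z0) / dz))
            stop = start + im.shape[2]
            out[:, :, start:stop] = np.maximum(out[:, :, start:stop], im.voxels)
    else:
        half = int(round(plan.overlap / dz / 2.0))
        n_slabs = len(slab_images)
        for i, (im, (lo, _)) in enumerate(zip(slab_images, plan.slabs)):
            a = 0 if i == 0 else half
            b = im.shape[2] if i == n_slabs - 1 else im.shape[2] - (
                int(round(plan.overlap / dz)) - half
            )
            start = int(round((lo - z0) / dz))
            out[:, :, start + a:start + b] = im.voxels[:, :, a:b]
    return ImageVolume(
        voxels=out,
        spacing=first.spacing,
        origin=(first.origin[0], first.origin[1], z0),
        meta=dict(first.meta),
    )


def add_kspace_noise(k: KSpaceVolume, sigma: float,
                     seed: Optional[int] = None) -> KSpaceVolume:
    """Add white complex Gaussian noise (std ``sigma`` per channel).

    After magnitude reconstruction the background becomes Rayleigh
    distributed (mean sigma*sqrt(pi/2) per voxel in k-space-noise units
    scaled by the FFT normalization).
    """
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    if sigma == 0:
        return KSpaceVolume(data=k.data.copy(), fov=k.fov, slab=k.slab,
                            meta=dict(k.meta))
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, sigma, k.data.shape) + 1j * rng.normal(
        0.0, sigma, k.data.shape
    )
    return KSpaceVolume(data=k.data + noise, fov=k.fov, slab=k.slab,
                        meta=dict(k.meta))
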