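"""Score a noisy volume against its clean reference.

Adds complex Gaussian noise to a synthetic k-space, reconstructs the
Rician-background magnitude image, denoises it with the 3D non-local
means filter, and prints the correlation / RMSE report (with the 95 %
Fisher-z confidence interval) before and after denoising.
"""

import numpy as np
from scipy.fft import fftn, fftshift, ifftshift

import tofsim as ts

rng = np.random.default_rng(0)
clean = np.zeros((32, 32, 16))
clean[10:22, 10:22, 4:12] = 1.0
clean += 0.1 * rng.random(clean.shape)  # mild texture

k = ts.KSpaceVolume(
    data=fftshift(fftn(ifftshift(clean))),
    fov=(32.0, 32.0, 16.0), slab=(0.0, 16.0),
)
noisy_img = ts.reconstruct_magnitude(ts.add_kspace_noise(k, sigma=6.0, seed=1))

snr = ts.estimate_snr(
    noisy_img.voxels,
    (slice(12, 20), slice(12, 20), slice(6, 10)),
    (slice(0, 6), slice(0, 6), slice(0, 4)),
)
print(f"background-based SNR      : {snr:5.1f}")

denoised = ts.nlm_denoise_3d(noisy_img.voxels, patch_radius=1,
                             search_radius=3)

for label, vol in [("noisy", noisy_img.voxels), ("denoised", denoised)]:
    rep = ts.compare_vois(vol, clean)
    print(f"{label:9s} vs clean: r = {rep.correlation:.4f} "
          f"[{rep.ci_lower:.4f}, {rep.ci_upper:.4f}], RMSE = {rep.rmse:.4f}")
print("\nNLM raises the correlation and lowers the scaled RMSE.")
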