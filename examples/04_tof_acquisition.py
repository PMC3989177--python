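"""Synthesize a small 3D time-of-flight acquisition and reconstruct it.

A short 8-mm tube is imaged with a reduced 64x64x16 matrix (16-mm slab
in the middle of the tube).  The printed per-slice lumen means show the
characteristic slab-entry signal void — spins that enter after the RF
pulse carry no transverse magnetization — followed by progressive
saturation deeper into the slab.
"""

import numpy as np

import tofsim as ts
from tofsim.engine import MovingComponent

geometry = ts.make_geometry({"kind": "straight", "diameter": 8.0, "length": 60.0})
field = ts.FlowField(geometry, flow_rate=2.5)
seeds = ts.sunflower_points(64, 4.0 * 0.995)
bundle = ts.trace_bundle(field, seeds, samples_per_trajectory=400)
areas = ts.voronoi_inlet_areas(seeds, 4.0)
seedings = ts.seed_trajectories(bundle, areas, 3.0)
component = MovingComponent(bundle=bundle, seedings=seedings,
                            tissue=ts.make_bmf(), flow_sign=1)

protocol = ts.Protocol(
    TE=4.7, TR=40.0, flip=np.deg2rad(20), matrix=(64, 64, 16),
    fov=(64.0, 64.0, 64.0), slab_width=16.0, slice_thickness=1.0,
)
slab = (22.0, 38.0)
print(f"simulating {protocol.matrix[1] * protocol.matrix[2]} TRs "
      f"({component.make_cloud().n_particles} particles) ...")
kspace = ts.simulate_slab([component], protocol, slab)
image = ts.reconstruct_magnitude(kspace)

xs = np.linspace(-32, 32, 64, endpoint=False) + 0.5
X, Y = np.meshgrid(xs, xs, indexing="ij")
lumen = np.hypot(X, Y) < 3.0
means = [image.voxels[lumen, i].mean() for i in range(16)]
print("\nmean lumen intensity per slice (entry -> exit):")
print("  " + " ".join(f"{m:.3f}" for m in means))
print("\nslice 0 (entry) is darker than the slab interior: spins arriving"
      "\nbetween excitation and readout have not been flipped yet.")
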