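"""Shared fixtures: small flow phantoms and cached acquisition runs.

The engine runs used by several behavioral tests are expensive (tens of
seconds), so they are session-scoped and reused.
"""

from __future__ import annotations

import numpy as np
import pytest

import tofsim as ts
from tofsim.engine import MovingComponent


TUBE_RADIUS = 4.0
TUBE_LENGTH = 60.0


def make_tube_component(flow_rate=2.5, n_traj=64, direction=1, origin=(0.0, 0.0, 0.0),
                        particles_per_mm=3.0, samples=400):
    """A short straight 8-mm tube along z with its seeded trajectory bundle."""
    g = ts.make_geometry(
        {"kind": "straight", "diameter": 2 * TUBE_RADIUS, "length": TUBE_LENGTH,
         "origin": list(origin)}
    )
    ff = ts.FlowField(g, flow_rate, direction=direction)
    seeds = ts.sunflower_points(n_traj, TUBE_RADIUS * 0.995)
    bundle = ts.trace_bundle(ff, seeds, samples_per_trajectory=samples)
    areas = ts.voronoi_inlet_areas(seeds, TUBE_RADIUS)
    seedings = ts.seed_trajectories(bundle, areas, particles_per_mm)
    return MovingComponent(bundle=bundle, seedings=seedings, tissue=ts.make_bmf(),
                           flow_sign=direction)


def lumen_mask(nx, fov, center_xy=(0.0, 0.0), radius=3.0):
    xs = np.linspace(-fov / 2, fov / 2, nx, endpoint=False) + fov / (2 * nx)
    X, Y = np.meshgrid(xs, xs, indexing="ij")
    return np.hypot(X - center_xy[0], Y - center_xy[1]) < radius


@pytest.fixture(scope="session")
def tube_component():
    return make_tube_component()


@pytest.fixture(scope="session")
def study_protocol_16():
    return ts.Protocol(
        TE=4.7, TR=40.0, flip=np.deg2rad(20), matrix=(64, 64, 16),
        fov=(64.0, 64.0, 64.0), slab_width=16.0, slice_thickness=1.0,
        readout_window=2.56,
    )


@pytest.fixture(scope="session")
def fast_flow_image(tube_component, study_protocol_16):
    """Scaled study-1-like acquisition of a fast-flow straight tube.

    The slab sits mid-tube so fresh fluid enters from below during the
    scan; used for entry-void and general contrast checks.
    """
    slab = (22.0, 38.0)
    k = ts.simulate_slab([tube_component], study_protocol_16, slab)
    img = ts.reconstruct_magnitude(k)
    return k, img


@pytest.fixture(scope="session")
def slow_flow_image(study_protocol_16):
    """Low-flow acquisition: strong in-slab saturation, parabolic profile."""
    comp = make_tube_component(flow_rate=0.3)
    slab = (22.0, 38.0)
    k = ts.simulate_slab([comp], study_protocol_16, slab)
    return k, ts.reconstruct_magnitude(k)


@pytest.fixture(scope="session")
def presat_images():
    """Two opposite-flow channels, with and without the saturation band."""
    co = make_tube_component(flow_rate=1.0, origin=(-12.0, 0.0, 0.0), direction=1)
    counter = make_tube_component(flow_rate=1.0, origin=(12.0, 0.0, 0.0), direction=-1)
    slab = (22.0, 38.0)
    proto = ts.Protocol(
        TE=4.7, TR=40.0, flip=np.deg2rad(20), matrix=(64, 64, 16),
        fov=(64.0, 64.0, 64.0), slab_width=16.0, slice_thickness=1.0,
        presat_enabled=True, presat_side="above", presat_width=40.0, presat_gap=5.0,
    )
    k = ts.simulate_slab([co, counter], proto, slab)
    return ts.reconstruct_magnitude(k)
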