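"""Shared fixtures. The expensive artifacts (rendered scans and the
reconstruction chains) are session-scoped and reused across test modules
to keep the suite within a single-core budget."""

from __future__ import annotations

import numpy as np
import pytest

from stoscan import (
    GridSpec,
    ScanGeometry,
    forward_project,
    reconstruct_fdk,
)
from stoscan.control import STO200_PROTOCOL
from stoscan.phantom import (
    REGULAR_BREATHER,
    generate_breathing_trace,
    make_phantom,
    phantom_volume,
)
from stoscan.simulate import NoiseModel, simulate_scan


@pytest.fixture(scope="session")
def geometry():
    return ScanGeometry()


@pytest.fixture(scope="session")
def grid():
    return GridSpec()


@pytest.fixture(scope="session")
def model():
    return make_phantom()


@pytest.fixture(scope="session")
def sphere_volume(grid):
    """Antialiased uniform sphere, R = 50 mm, mu = 0.02 / mm."""
    from stoscan.grids import Volume3D

    ax = grid.axes()
    X, Y, Z = np.meshgrid(*ax, indexing="ij")
    r = np.sqrt(X ** 2 + Y ** 2 + Z ** 2)
    vox = 0.02 * np.clip((50.0 - r) / 4.0 + 0.5, 0.0, 1.0)
    return Volume3D(vox.astype(np.float32), grid.spacing, grid.origin)


@pytest.fixture(scope="session")
def static_projections(model, geometry, grid):
    """200 projections of the mid-displacement phantom over the arc,
    labeled with the ideal interleaved bin sequence."""
    vol = phantom_volume(model, 0.5, grid)
    angles = np.arange(200) * 1.0 + 0.5
    bins = (np.arange(200) % 10) + 1
    return forward_project(vol, geometry, angles, bins=bins)


@pytest.fixture(scope="session")
def static_fdk(static_projections, grid):
    return reconstruct_fdk(static_projections, grid)


@pytest.fixture(scope="session")
def regular_trace():
    return generate_breathing_trace(REGULAR_BREATHER, 120.0, 1)


@pytest.fixture(scope="session")
def sto200_sim(model, regular_trace, geometry, grid):
    """Closed-loop STO200 scan of the breathing phantom, rendered, with
    the default photon-noise model."""
    return simulate_scan(model, regular_trace, STO200_PROTOCOL, geometry,
                         None, grid, seed=1, noise=NoiseModel(seed=1),
                         render=True)


@pytest.fixture(scope="session")
def sto200_sim_fast(model, regular_trace, geometry, grid):
    """Same closed loop without rendering (schedule/trajectory only)."""
    return simulate_scan(model, regular_trace, STO200_PROTOCOL, geometry,
                         None, grid, seed=1, render=False)


def nrms(a, b):
    return float(np.linalg.norm(np.asarray(a, float) - np.asarray(b, float))
                 / np.linalg.norm(np.asarray(b, float)))


@pytest.fixture(scope="session")
def mean_bin_displacements(sto200_sim, regular_trace):
    """Mean normalized displacement of the projections in each bin."""
    sched = sto200_sim.schedule
    out = {}
    for j in range(1, 11):
        ts = sched.times_s[sched.bins == j]
        out[j] = float(np.mean([regular_trace.sample_at(float(t))[1]
                                for t in ts]))
    return out
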