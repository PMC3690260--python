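"""Shared fixtures.

The heavy session fixtures reproduce the reference study conditions: a
200-view, 1 deg/view circular short scan over 4 s of the breathing thorax
phantom (23 mm peak-to-peak SI motion), with reconstructions on a 128^3 grid
at 2 mm. They are instantiated lazily, so cheap unit tests never pay for them.
"""

from __future__ import annotations

import numpy as np
import pytest

from diamoco.geometry import DetectorSpec, make_circular_trajectory, project_point
from diamoco.reconstruction import Grid, backproject, filter_projections
from diamoco.simulator import (
    breathing_displacement,
    default_phantom,
    diaphragm_top_truth,
    forward_project,
)
from diamoco.tracking import TrackingConfig, track_sequence


@pytest.fixture(scope="session")
def geom200():
    return make_circular_trajectory(n_views=200, increment=1.0, sod=800.0, sdd=1200.0, scan_time=4.0)


@pytest.fixture(scope="session")
def phantom():
    return default_phantom(amplitude_mm=23.0, period_s=4.0)


@pytest.fixture(scope="session")
def static_phantom():
    return default_phantom(amplitude_mm=0.0, period_s=4.0)


@pytest.fixture(scope="session")
def moving_stack(phantom, geom200):
    return forward_project(phantom, geom200)


@pytest.fixture(scope="session")
def static_stack(static_phantom, geom200):
    return forward_project(static_phantom, geom200)


@pytest.fixture(scope="session")
def apex_projections(phantom, geom200):
    """Exact per-view projections of the true diaphragm apex."""
    return np.asarray(
        [
            project_point(geom200.matrices[i], diaphragm_top_truth(phantom, t))
            for i, t in enumerate(geom200.timestamps)
        ]
    )


@pytest.fixture(scope="session")
def track_results(moving_stack, apex_projections, geom200):
    seed = apex_projections[0] + np.array([3.0, -2.0])  # a user clicks roughly
    return track_sequence(
        moving_stack, seed, TrackingConfig(), rng_seed=1, angles_deg=geom200.angles
    )


@pytest.fixture(scope="session")
def recon_grid():
    return Grid(shape=(128, 128, 128), spacing=(2.0, 2.0, 2.0))


@pytest.fixture(scope="session")
def recon_volumes(phantom, geom200, moving_stack, static_stack, recon_grid):
    """Reference (static-scan), uncompensated and compensated reconstructions."""
    true_signal = breathing_displacement(geom200.timestamps, phantom)
    filt_static = filter_projections(static_stack, geom200)
    filt_moving = filter_projections(moving_stack, geom200)
    return {
        "ref": backproject(filt_static, geom200, None, recon_grid),
        "unc": backproject(filt_moving, geom200, None, recon_grid),
        "cmp": backproject(filt_moving, geom200, true_signal, recon_grid),
        "signal": true_signal,
    }


@pytest.fixture(scope="session")
def small_detector():
    return DetectorSpec(nu=160, nv=120, spacing_u=2.464, spacing_v=2.464)


@pytest.fixture(scope="session")
def small_geom(small_detector):
    return make_circular_trajectory(
        n_views=20, increment=10.0, sod=800.0, sdd=1200.0, scan_time=4.0, detector=small_detector
    )
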