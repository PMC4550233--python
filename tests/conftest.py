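"""Shared fixtures: optical/camera configs and rendered synthetic stacks.

Session-scoped renders are shared across test modules to keep the suite
fast; every render is seed-pinned and therefore reproducible.
"""

import numpy as np
import pytest

import spintirf as st
from spintirf.sim_camera import PUFF_SCAN_RADIUS, puff_event_windows


@pytest.fixture(scope="session")
def optics():
    return st.OpticalConfig()


@pytest.fixture(scope="session")
def camera():
    return st.CameraModel()


@pytest.fixture(scope="session")
def speckle():
    return st.SpeckleModel(seed=3)


@pytest.fixture(scope="session")
def film_stability_stack(optics, camera):
    """600 spinning-spot frames of a uniform film at ~100 photons/pixel."""
    specimen, schedule = st.make_scenario(
        "film_beads", seed=1, n_beads=0, modes=["spinning_tirf"], n_frames=600
    )
    return st.render_stack(specimen, schedule, optics, camera, seed=1)


@pytest.fixture(scope="session")
def interleaved_film_stack(optics, camera):
    """200 frames alternating stationary- and spinning-spot TIRF of a film."""
    specimen, schedule = st.make_scenario(
        "film_beads", seed=3, n_beads=0,
        modes=["stationary_tirf", "spinning_tirf"], n_frames=200,
    )
    return st.render_stack(specimen, schedule, optics, camera, seed=3)


@pytest.fixture(scope="session")
def puff_recording(optics, camera):
    """Interleaved TIRF/WF recording of six sites at depths 0-500 nm.

    Returns (stack, specimen, rois, event windows, penetration depth).
    """
    depths = [0.0, 100.0, 200.0, 300.0, 400.0, 500.0]
    specimen, schedule = st.make_scenario(
        "puff_depths", seed=5, depths_nm=depths, n_events=20
    )
    stack = st.render_stack(specimen, schedule, optics, camera, seed=5)
    px = camera.pixel_size_um
    ny, nx = camera.frame_shape
    rois, events = [], {}
    for i, site in enumerate(specimen.puff_sites):
        cx = int(round(site.x_um / px + (nx - 1) / 2))
        cy = int(round(site.y_um / px + (ny - 1) / 2))
        roi = st.ROI.centered(f"site{i}", cx, cy, 3, group=f"g{i}")
        rois.append(roi)
        events[roi.label] = puff_event_windows(site)
    d_nm = st.depth_for_scan_radius(PUFF_SCAN_RADIUS, st.OpticalConfig())
    return stack, specimen, rois, events, d_nm


@pytest.fixture(scope="session")
def puff_analysis_result(puff_recording):
    from spintirf.puff_analysis import analyze_interleaved

    stack, specimen, rois, events, d_nm = puff_recording
    return analyze_interleaved(
        stack, rois, events, baseline_range=(0, 100), depth_nm=d_nm
    )
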