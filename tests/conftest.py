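"""Shared fixtures: canonical optics, cached simulations and libraries.

The expensive simulations (the 51-plane rotation analysis and the small
template library) are session-scoped so the whole suite pays for them
once.
"""

from __future__ import annotations

import numpy as np
import pytest

import ssrpsf as S


@pytest.fixture(scope="session")
def system() -> S.OpticalSystem:
    return S.OpticalSystem()


@pytest.fixture(scope="session")
def design() -> S.SPPDesign:
    return S.SPPDesign()


@pytest.fixture(scope="session")
def small_grid() -> S.SimulationGrid:
    return S.SimulationGrid(n_fft=512, oversample=3)


@pytest.fixture(scope="session")
def rotation_analysis(system, design):
    """Hotspot trajectory of the canonical simulated stack, dz -2..+3 um in
    0.1-um steps, extracted at the transform's native sampling."""
    zs = np.round(np.arange(-2.0, 3.0001, 0.1), 9)
    stack = S.simulate_stack(
        (0.0, 0.0), zs, system, design,
        grid=S.SimulationGrid(1024, 3), out_pixels=51, binned=False,
    )
    track = S.extract_hotspot_track(stack, method="max_pixel", dz_range=None)
    circle = S.fit_circle(track.xy)
    angles = S.angle_series(track, circle.center)
    ror = S.fit_ror(angles, track.dz)
    return {"track": track, "circle": circle, "angles": angles, "ror": ror}


@pytest.fixture(scope="session")
def small_library(system, design, small_grid) -> S.TemplateLibrary:
    """21-plane template library, dz -1..+1 um in 100-nm steps, 51x51 px."""
    labels = np.round(np.arange(-1.0, 1.0001, 0.1), 9)
    stack = S.simulate_stack((0.0, 0.0), labels, system, design, grid=small_grid, out_pixels=51)
    return S.TemplateLibrary(stack.planes, labels, system.sample_pixel)


@pytest.fixture(scope="session")
def focal_image(system, design, small_grid) -> S.CameraImage:
    """Noiseless unit-budget focal-plane camera frame."""
    return S.image_of_point(S.EmitterPose(), system, design, small_grid, out_pixels=51)
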