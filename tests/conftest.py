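"""Shared fixtures: geometries, render grids, and cached synthetic stacks."""

from __future__ import annotations

import numpy as np
import pytest

import ctiq
from ctiq.core import InsertSpec, PhantomGeometry


@pytest.fixture(scope="session")
def geometry():
    """Full Catphan-style geometry on a 160 mm field of view."""
    return ctiq.default_geometry(fov_mm=160.0)


@pytest.fixture(scope="session")
def grid():
    """Default render grid matching the session geometry's FOV."""
    return ctiq.RenderGrid(n_pixels=320, pixel_spacing_mm=0.5)


@pytest.fixture(scope="session")
def fine_grid():
    """Small-FOV fine grid (40 mm at 0.1 mm pixels) for resolution work."""
    return ctiq.RenderGrid(n_pixels=400, pixel_spacing_mm=0.1)


@pytest.fixture(scope="session")
def single_insert_geometry():
    """One centred 14 mm insert in a small phantom, for ESF/TTF tests."""
    ins = InsertSpec("teflon", (0.0, 0.0), 14.0, 990.0)
    return PhantomGeometry(
        phantom_center={"sensitometry": (20.0, 20.0)},
        module_z={"sensitometry": (-5.0, 5.0)},
        phantom_radius=19.0,
        inserts=[ins],
    )


@pytest.fixture(scope="session")
def noisy_uniformity_stack(geometry, grid):
    """Uniformity module, white noise sigma=10, radial cupping field."""
    truth = ctiq.GroundTruth(
        background_hu=20.0,
        noise_sigma_hu=10.0,
        radial_coeffs=(0.0, 0.0, 5.0 / 55.0**2),  # +5 HU at r=55 mm
        seed=20240901,
    )
    stack, _ = ctiq.render_module(geometry, "uniformity", truth, grid, n_slices=5)
    return stack, truth


def make_flat_stack(value: float, shape=(1, 32, 32), spacing=(0.5, 0.5)) -> ctiq.ImageStack:
    return ctiq.ImageStack(
        voxels=np.full(shape, float(value)),
        pixel_spacing=spacing,
        z_positions=np.arange(shape[0], dtype=float),
    )


@pytest.fixture
def flat_stack():
    return make_flat_stack(100.0)
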