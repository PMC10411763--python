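"""Shared fixtures: small phantoms and registration test objects.

Expensive objects are session-scoped; tests must not mutate them.
"""
from __future__ import annotations

import numpy as np
import pytest

import voxdose as vd


@pytest.fixture(scope="session")
def small_spec() -> vd.PhantomSpec:
    """Compact phantom for registration tests: 48³ grid, 60-mm cylinder."""
    return vd.PhantomSpec(
        cylinder_radius=60.0,
        cylinder_height=120.0,
        sphere_radii=(8.0, 12.0),
        sphere_ring_radius=35.0,
        sphere_plane_z=18.0,
        rod_sector_diameters=(8.0, 12.0),
        rod_region_radius=50.0,
        rod_z_range=(-55.0, -5.0),
        fiducial=vd.FiducialSpec(position_mm=(75.0, 0.0, 0.0)),
        grid_shape=(48, 48, 48),
        voxel_spacing=(4.0, 4.0, 4.0),
    )


@pytest.fixture(scope="session")
def small_phantom(small_spec):
    activity, ct = vd.make_phantom(small_spec)
    return activity, ct


@pytest.fixture(scope="session")
def small_reference(small_phantom):
    """Blurred, noiseless acquisition of the unrotated small phantom."""
    activity, _ = small_phantom
    return vd.simulate_acquisition(activity, psf_fwhm_mm=10.0, total_counts=6.0e6,
                                   poisson=False)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def random_volume(rng, shape=(8, 8, 8), spacing=(4.0, 4.0, 4.0), kind=vd.ValueKind.COUNTS):
    return vd.Volume3D(rng.random(shape) * 100.0, spacing,
                       tuple(-(n - 1) / 2.0 * s for n, s in zip(shape, spacing)),
                       value_kind=kind)
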