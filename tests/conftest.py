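"""Shared fixtures: one small desk-scale scanner/phantom pair reused across
the suite so the (cached) system matrices are built only once."""

import pytest

from pedpet import ScannerGeometry, simulate_listmode
from pedpet.protocol import default_vois, standard_phantom


@pytest.fixture(scope="session")
def small_geometry():
    return ScannerGeometry(n_angles=28, n_radial_bins=64, radial_bin_size=4.073)


@pytest.fixture(scope="session")
def small_phantom():
    return standard_phantom(body_diameter=200.0, n_image=64, voxel_size=4.073)


@pytest.fixture(scope="session")
def small_vois(small_phantom):
    return default_vois(small_phantom)


@pytest.fixture(scope="session")
def small_listmode(small_phantom, small_geometry):
    return simulate_listmode(small_phantom, small_geometry,
                             target_prompts=500_000, seed=7)


@pytest.fixture(scope="session")
def uniform_disc_phantom():
    """Lesion-free uniform disc (circular body) for analytic projections."""
    from pedpet import PhantomSpec, make_phantom

    spec = PhantomSpec(body_diameter=160.0, background_uptake=1.0,
                       body_aspect=1.0)
    return make_phantom(spec, n_image=64, voxel_size=4.073)
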