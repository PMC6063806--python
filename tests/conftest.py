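"""Shared fixtures: a small fast geometry for unit tests and the default
desk-scale phantom/sinogram (session-scoped, reused by the heavier tests)."""

from __future__ import annotations

import numpy as np
import pytest

from rdpet import (
    Lesion,
    NoiseSpec,
    PhantomSpec,
    Sphere,
    default_pelvic_spec,
    make_pelvic_phantom,
    simulate_sinogram,
)
from rdpet.calibrate import DEFAULT_COUNT_SCALE
from rdpet.system_model import ScannerGeometry, SystemModel


@pytest.fixture(scope="session")
def small_geometry() -> ScannerGeometry:
    return ScannerGeometry(
        grid_shape=(32, 32, 4),
        voxel_size_mm=(6.0, 6.0, 6.0),
        n_angles=24,
        n_radial=48,
        radial_spacing_mm=6.0,
        n_tof_bins=5,
        tof_fwhm_mm=60.0,
        psf_fwhm_mm=5.4,
        count_scale=0.5,
    )


@pytest.fixture(scope="session")
def small_phantom(small_geometry):
    spec = PhantomSpec(
        grid_shape=small_geometry.grid_shape,
        voxel_size_mm=small_geometry.voxel_size_mm,
        body_axes_mm=(80.0, 70.0),
        bladder=Sphere((0.0, -25.0, 0.0), 15.0, 7.7),
        lesions=(Lesion("l1", (35.0, 15.0, 0.0), 9.0, 8.0),),
        background_roi=Sphere((-35.0, -25.0, 0.0), 12.0),
    )
    return make_pelvic_phantom(spec)


@pytest.fixture(scope="session")
def small_sinogram(small_phantom, small_geometry):
    return simulate_sinogram(small_phantom, small_geometry, NoiseSpec(rng_seed=1))


@pytest.fixture(scope="session")
def small_system(small_sinogram):
    return SystemModel(
        small_sinogram.geometry,
        atten=small_sinogram.atten,
        norm=small_sinogram.norm,
    )


@pytest.fixture(scope="session")
def default_geometry_fx() -> ScannerGeometry:
    return ScannerGeometry(count_scale=DEFAULT_COUNT_SCALE)


@pytest.fixture(scope="session")
def default_phantom():
    return make_pelvic_phantom(default_pelvic_spec())


@pytest.fixture(scope="session")
def default_sinogram(default_phantom, default_geometry_fx):
    return simulate_sinogram(default_phantom, default_geometry_fx, NoiseSpec(rng_seed=0))


@pytest.fixture(scope="session")
def default_system(default_sinogram):
    return SystemModel(
        default_sinogram.geometry,
        atten=default_sinogram.atten,
        norm=default_sinogram.norm,
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
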