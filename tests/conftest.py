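import numpy as np
import pytest

from nucleomorph import generate_nucleus
from nucleomorph.phantom import NucleusSpec, PhantomSpec


def clean_spec(semi_axes_um, shape, center, angles=(0, 0, 0), spacing=(150.0, 120.0, 120.0)):
    """Noise-free, texture-free, blur-free phantom spec for shape oracles."""
    return PhantomSpec(
        shape=shape,
        nuclei=(NucleusSpec(semi_axes_um, center, angles),),
        spacing_nm=spacing,
        texture_amplitude=0.0,
        gaussian_noise_sd=0.0,
        psf_sigma_nm=(0.0, 0.0, 0.0),
        background=0.0,
        seed=0,
    )


@pytest.fixture(scope="session")
def sphere_phantom():
    """Voxelized solid sphere, r = 3 µm, acquisition spacing, no noise."""
    return generate_nucleus(clean_spec((3.0, 3.0, 3.0), (60, 70, 70), (30, 35, 35)))


@pytest.fixture(scope="session")
def ellipsoid_phantom():
    """Voxelized solid ellipsoid (6, 4, 2) µm, axis-aligned (r1 along z)."""
    return generate_nucleus(clean_spec((6.0, 4.0, 2.0), (88, 78, 46), (44, 39, 23)))


@pytest.fixture(scope="session")
def rotated_ellipsoid_phantom():
    """Same (6, 4, 2) µm ellipsoid rotated by 30 degrees about x."""
    return generate_nucleus(
        clean_spec((6.0, 4.0, 2.0), (92, 92, 46), (46, 46, 23), angles=(0, 0, 30))
    )


@pytest.fixture(scope="session")
def noisy_nucleus():
    """Small textured, blurred, noisy nucleus for pipeline-level tests."""
    spec = PhantomSpec(
        shape=(30, 64, 64),
        nuclei=(NucleusSpec((1.6, 1.3, 1.1), (15, 32, 32), (20, 10, 5)),),
        gaussian_noise_sd=0.02,
        seed=11,
    )
    return generate_nucleus(spec)
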