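import numpy as np
import pytest

from osteomip import (
    DensityPatch,
    MalleolusSpec,
    PhantomSpec,
    generate_epiphysis_phantom,
    study_fixture_tables,
    study_fixture_tree,
)


@pytest.fixture(scope="session")
def patch_spec():
    """Phantom with one high-density patch whose peak falls in the top bin."""
    return PhantomSpec(
        grid_shape=(48, 40, 40),
        voxel_spacing=(0.5, 0.5, 0.5),
        density_patches=(DensityPatch((20.0, 20.0), 4.0, 250.0),),
        plate_base_value=100.0,
        trabecular_value=60.0,
        noise_sd=0.0,
        seed=11,
    )


@pytest.fixture(scope="session")
def patch_phantom(patch_spec):
    return generate_epiphysis_phantom(patch_spec)


@pytest.fixture(scope="session")
def flange_spec():
    """Phantom with a steep malleolus-like flange on one side."""
    return PhantomSpec(
        grid_shape=(48, 40, 40),
        voxel_spacing=(0.5, 0.5, 0.5),
        surface_profile=(10.0, 0.0, 0.0, 0.0),
        malleolus=MalleolusSpec(position=30, width_mm=5.0, drop_depth_mm=8.0),
        noise_sd=0.0,
        seed=7,
    )


@pytest.fixture(scope="session")
def flange_phantom(flange_spec):
    return generate_epiphysis_phantom(flange_spec)


@pytest.fixture(scope="session")
def species_table():
    return study_fixture_tables()[0]


@pytest.fixture(scope="session")
def group_table():
    return study_fixture_tables()[1]


@pytest.fixture(scope="session")
def fixture_tree():
    return study_fixture_tree()


def random_volume(rng, shape=None):
    """Small random radiodensity volume for oracle comparisons."""
    shape = shape or tuple(rng.integers(4, 33, size=3))
    return rng.uniform(0.0, 300.0, size=shape)
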