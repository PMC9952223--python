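import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from callusim import (  # noqa: E402
    VoxelLattice,
    VoxelModel,
    default_materials,
    preset_config,
    run_simulation,
)


@pytest.fixture(scope="session")
def materials():
    return default_materials()


@pytest.fixture()
def small_lattice():
    return VoxelLattice(extents=(6, 6, 6))


@pytest.fixture()
def single_element_model(small_lattice):
    model = VoxelModel(small_lattice)
    model.add_element((2, 2, 2), "callus", fragment_id=1)
    return model


def random_blob_model(rng, shape=(5, 5, 5), fill=0.5, material="cortical"):
    """A random connected-ish voxel blob used by several oracle tests."""
    lattice = VoxelLattice(extents=shape)
    model = VoxelModel(lattice)
    for site in np.argwhere(rng.random(shape) < fill):
        model.add_element(site, material, fragment_id=1)
    return model


@pytest.fixture(scope="session")
def transverse_result():
    """One full transverse-preset run shared by the scenario-level tests."""
    return run_simulation(preset_config("transverse"))
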