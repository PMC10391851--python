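import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("default", derandomize=True, max_examples=50)
settings.load_profile("default")


@pytest.fixture(scope="session")
def default_grid():
    """The full 27-cell factorial grid at default 1 mm voxel size.

    Session-scoped: the grid takes a few minutes and several tests only read
    from it.
    """
    from cervifem import experiment

    return experiment.run_grid()


@pytest.fixture()
def rng():
    return np.random.default_rng(20230801)


def make_bar_model(nx, ny, nz, role, voxel_size=1.0):
    """Uniform rectangular bar of a single material, as a LabeledVoxelModel."""
    from cervifem.geometry import ROLE_CODES, LabeledVoxelModel

    labels = np.full((nx, ny, nz), ROLE_CODES[role], dtype=np.int8)
    return LabeledVoxelModel(labels=labels, voxel_size=voxel_size,
                             level_spans={"C5": (0, nz)}, surgery="BAR")
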