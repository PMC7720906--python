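import pytest
from hypothesis import settings

import ramanmc as rm

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def emission_grid():
    return rm.emission_grid()


@pytest.fixture(scope="session")
def tiny_depth_fixture():
    """Small homogeneous slab for fast engine tests (32^3 voxels, 2 cm)."""
    return rm.make_depth_medium(0.01, 1.0, 1e-3, n_voxels=32)


@pytest.fixture(scope="session")
def two_layer_fixture():
    """Scaled-down two-layer phantom replica (exercises every event branch)."""
    return rm.make_phantom("III", n_voxels=40, rho_R_scale=5e-3, rho_F_scale=5e-3)


@pytest.fixture(scope="session")
def warm_kernel(tiny_depth_fixture):
    """Compile the batch kernel once per session."""
    rm.run_simulation(tiny_depth_fixture.run_config(50, 1, seed=0))
    return True
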