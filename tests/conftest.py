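import numpy as np
import pytest

from trabsim.grid import init_tissue_state
from trabsim.synthgen import PhantomSpec, make_trabecular_phantom


@pytest.fixture(scope="session")
def small_phantom():
    """24^3 Gaussian-field phantom shared by integration-level tests."""
    spec = PhantomSpec(
        shape=(24, 24, 24), target_bvtv=0.2, rng_seed=1,
        ivd_pad_height=2, cortical_shell_thickness=2,
    )
    return make_trabecular_phantom(spec)


@pytest.fixture(scope="session")
def bone_block():
    """Homogeneous 12^3 all-bone grid for FE checks."""
    return init_tissue_state(np.ones((12, 12, 12), dtype=bool))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
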