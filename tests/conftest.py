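import numpy as np
import pytest

from hmdcalib import synthetic_data as sd


@pytest.fixture(scope="session")
def phantom():
    return sd.generate_phantom(1, 42)


@pytest.fixture(scope="session")
def truth_template(phantom):
    return sd.render_template(phantom, "truth")


@pytest.fixture(scope="session")
def zero_noise_model():
    return sd.UserErrorModel("TC", 0.0, 0.0, 71, 23)


@pytest.fixture(scope="session")
def zero_noise_trial(phantom, zero_noise_model):
    return sd.simulate_trial(phantom, zero_noise_model, seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform-ish random proper rotation via a random rotation vector."""
    from scipy.spatial.transform import Rotation

    return Rotation.from_rotvec(rng.normal(size=3)).as_matrix()
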