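import numpy as np
import pytest

from dispercann.constitutive import ModelWeights
from dispercann.dispersion import DispersionParams


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def random_weights(rng):
    """A dense random admissible weight set (all 48 weights in [0, 0.5])."""
    return ModelWeights.from_vector(rng.uniform(0.0, 0.5, 48))


@pytest.fixture
def second_order_weights(rng):
    """Random weights whose first-order anisotropic terms vanish.

    Linear and exp-linear nodes of the I4*/I8 rows have nonzero energy
    derivatives at F = I that no hydrostatic pressure can cancel; models
    without them have a stress-free reference state.
    """
    w = ModelWeights.from_vector(rng.uniform(0.0, 0.5, 48))
    w.lin1[2:] = 0.0
    w.exp1[2:, :] = 0.0
    return w


@pytest.fixture
def kappas():
    return DispersionParams(0.1, 0.2, 0.05)


@pytest.fixture
def random_rotations(rng):
    """A batch of random proper rotation matrices via QR decomposition."""
    mats = []
    for _ in range(8):
        Q, R = np.linalg.qr(rng.normal(size=(3, 3)))
        Q = Q * np.sign(np.diag(R))
        if np.linalg.det(Q) < 0:
            Q[:, 0] = -Q[:, 0]
        mats.append(Q)
    return mats
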