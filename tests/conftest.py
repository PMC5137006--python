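import numpy as np
import pytest

from turntilt import (
    DEFAULT_PARAMS,
    Conformation,
    build_backbone,
    default_transform,
)
from turntilt.transform import basin_maps


@pytest.fixture(scope="session")
def maps():
    """The 1-degree S / rho / theta sweep maps (computed once)."""
    return basin_maps(1.0)


@pytest.fixture(scope="session")
def transform(maps):
    """The affine (phi,psi) -> (rho,theta) transform over S > 0."""
    return default_transform(1.0)


@pytest.fixture(scope="session")
def alpha_chain():
    """A 30-residue backbone at the classic alpha-helix conformation."""
    return build_backbone(DEFAULT_PARAMS, Conformation(-57.0, -47.0))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_rotation(rng):
    """A uniformly random proper rotation matrix."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])
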