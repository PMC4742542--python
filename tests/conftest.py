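import numpy as np
import pytest

from dwiphantom import (
    FixtureSpec,
    generate_uniform_scheme,
    make_crossing_slab,
    make_mini_brain,
    make_single_voxel,
)

Z = np.array([0.0, 0.0, 1.0])
X = np.array([1.0, 0.0, 0.0])


@pytest.fixture(scope="session")
def scheme30():
    """30-direction b=1000 shell + 1 b0; small restart budget keeps tests fast."""
    return generate_uniform_scheme([30], [1000.0], n_b0=1, seed=7, restarts=3)


@pytest.fixture(scope="session")
def scheme_two_shell():
    return generate_uniform_scheme([12, 12], [700.0, 2000.0], n_b0=2, seed=3, restarts=2)


@pytest.fixture(scope="session")
def mini_brain():
    return make_mini_brain(FixtureSpec(kind="mini_brain", shape=(32, 32, 32)))


@pytest.fixture(scope="session")
def crossing_slab_60():
    return make_crossing_slab(
        FixtureSpec(kind="crossing_slab", shape=(16, 16, 8), crossing_angle=60.0)
    )


@pytest.fixture()
def mixed_voxel():
    """The canonical test voxel: 0.7 fiber along z + 0.2 WM + 0.1 CSF."""
    return make_single_voxel({"F1": 0.7, "WM": 0.2, "CSF": 0.1}, {"F1": Z})
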