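import numpy as np
import pytest

from comap.geography import build_adjacency
from comap.synthetic import lattice_map


@pytest.fixture(scope="session")
def lattice98():
    return lattice_map()


@pytest.fixture(scope="session")
def graph4():
    """2x2 rook lattice: a - b, a - c, b - d, c - d."""
    return build_adjacency(
        [("a", "b"), ("a", "c"), ("b", "d"), ("c", "d")], ["a", "b", "c", "d"]
    )


@pytest.fixture(scope="session")
def path3():
    """Path graph on three areas: a - b - c."""
    return build_adjacency([("a", "b"), ("b", "c")], ["a", "b", "c"])


@pytest.fixture(scope="session")
def pair2():
    """Two linked areas."""
    return build_adjacency([("a", "b")], ["a", "b"])


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
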