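import numpy as np
import pytest

from neuroturb import euclidean_distances
from neuroturb.io import DistanceMatrix, Parcellation
from neuroturb.phases import PhaseMatrix
from neuroturb.synth import gen_parcellation


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


@pytest.fixture
def small_parcellation():
    """20 random nodes, enough geometry for every pairwise measure."""
    return gen_parcellation(20, seed=42)


@pytest.fixture
def small_distances(small_parcellation):
    return euclidean_distances(small_parcellation)


@pytest.fixture
def random_phases(rng):
    """15 nodes x 40 time points of uniform random phases."""
    return PhaseMatrix(
        rng.uniform(0, 2 * np.pi, size=(15, 40)), tr_seconds=2.0
    )


def make_distance_matrix(coords):
    return euclidean_distances(Parcellation(np.asarray(coords, dtype=float)))
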