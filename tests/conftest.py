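import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform

from dthtest import DistanceMatrix, GroupLabels


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


@pytest.fixture
def euclid_toy(rng):
    """16 points in 4-d, two balanced groups, Euclidean distance matrix."""
    pts = rng.normal(size=(16, 4))
    D = DistanceMatrix(squareform(pdist(pts)))
    labels = GroupLabels(["a"] * 8 + ["b"] * 8)
    return pts, D, labels


@pytest.fixture
def three_group_toy(rng):
    pts = rng.normal(size=(15, 3))
    D = DistanceMatrix(squareform(pdist(pts)))
    labels = GroupLabels(["a"] * 5 + ["b"] * 5 + ["c"] * 5)
    return D, labels
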