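import numpy as np
import pytest

from lesionctl.types import Connectome


def make_connectome(adjacency, hemisphere=None, volumes=None, lesion=None,
                    labels=None):
    """Small-connectome builder for tests."""
    a = np.asarray(adjacency, dtype=float)
    n = a.shape[0]
    if labels is None:
        labels = [f"n{i}" for i in range(n)]
    if hemisphere is None:
        hemisphere = ["L"] * (n // 2) + ["R"] * (n - n // 2)
    if volumes is None:
        volumes = np.full(n, 1000.0)
    if lesion is None:
        lesion = np.zeros(n)
    return Connectome(
        node_ids=labels,
        hemisphere=np.array(hemisphere, dtype=object),
        adjacency=a,
        region_volume=np.asarray(volumes, dtype=float),
        region_lesion_fraction=np.asarray(lesion, dtype=float),
    )


def random_symmetric(n, rng, density=0.5, scale=1.0):
    mask = np.triu(rng.random((n, n)) < density, k=1)
    a = np.zeros((n, n))
    a[mask] = rng.uniform(0.1, 1.0, mask.sum()) * scale
    return a + a.T


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def path_plus_chords():
    """Connected 10-node path plus two chords with generic random weights."""
    n = 10
    r = np.random.default_rng(5)
    a = np.zeros((n, n))
    edges = [(i, i + 1) for i in range(n - 1)] + [(0, 5), (2, 8)]
    for i, j in edges:
        a[i, j] = a[j, i] = r.uniform(0.5, 1.5)
    return make_connectome(a)
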