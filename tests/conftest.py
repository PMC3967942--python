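import itertools

import numpy as np
import pytest

from comparanet import Connectome, fig1d_toy, random_connectome
from comparanet.synthetic import default_labels


def connectome_from_edges(labels, edges, weights=None):
    """Build an undirected connectome from unordered label pairs."""
    labels = tuple(labels)
    pos = {lab: i for i, lab in enumerate(labels)}
    n = len(labels)
    w = np.zeros((n, n))
    for idx, (u, v) in enumerate(edges):
        val = 1.0 if weights is None else float(weights[idx])
        w[pos[u], pos[v]] = w[pos[v], pos[u]] = val
    return Connectome(labels, w, directed=False, weighted=weights is not None)


def all_graphs(n):
    """Yield every labeled undirected graph on n nodes as a Connectome."""
    labels = default_labels(n)
    pairs = list(itertools.combinations(range(n), 2))
    for bits in range(2 ** len(pairs)):
        w = np.zeros((n, n))
        for k, (i, j) in enumerate(pairs):
            if bits >> k & 1:
                w[i, j] = w[j, i] = 1.0
        yield Connectome(labels, w)


@pytest.fixture(scope="session")
def toy_pair():
    return fig1d_toy()


@pytest.fixture(scope="session")
def brain_sized():
    """82-node binary fixture at the whole-brain density."""
    return random_connectome(82, 1857, seed=20240101)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
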