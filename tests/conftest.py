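import numpy as np
import pytest

from abnet import (
    AdjacencyMatrix,
    BandMatrix,
    CorrelationMatrix,
    load_fixture,
)


@pytest.fixture(scope="session")
def printed():
    """The packaged published tables (global attributes, N/M/I/rank, ledgers)."""
    return load_fixture()


@pytest.fixture
def rng():
    return np.random.default_rng(20150317)


def make_band_matrix(values, group="test", band_ids=None):
    values = np.asarray(values)
    n, k = values.shape
    return BandMatrix(
        values=values,
        band_ids=np.arange(1, k + 1) if band_ids is None else np.asarray(band_ids),
        participant_ids=tuple(f"p{i}" for i in range(n)),
        group=group,
    )


def adjacency_from_edges(n_nodes, edges, band_ids=None, alpha=0.05):
    """Build an AdjacencyMatrix from unique (i, j) band-id pairs."""
    ids = np.arange(1, n_nodes + 1) if band_ids is None else np.asarray(band_ids)
    pos = {int(b): i for i, b in enumerate(ids)}
    b = np.zeros((n_nodes, n_nodes), dtype=np.int8)
    for u, v in edges:
        b[pos[u], pos[v]] = b[pos[v], pos[u]] = 1
    return AdjacencyMatrix(b=b, alpha=alpha, band_ids=ids)


def correlation_from_matrix(r, n=50, band_ids=None):
    r = np.asarray(r, dtype=float)
    k = r.shape[0]
    ids = np.arange(1, k + 1) if band_ids is None else np.asarray(band_ids)
    return CorrelationMatrix(
        r=r, defined=~np.isnan(r), n=n, band_ids=ids
    )
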