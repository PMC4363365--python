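"""The connection-intensity statistic I = N x M, per node and per group.

For each band (node): N is its number of significant correlations (its
degree in the adjacency B), M is the *signed* mean of the Pearson
coefficients over those N significant pairs (M = 0 when N = 0), and
I = N * M.  Nodes are ranked by descending I, ties broken by ascending
band id.  The signed mean matters: a node can carry many weak or opposed
correlations (large N, near-zero or negative M) and still rank low.

At the group level N_k is the total number of ones in B, M_k the signed
mean of r over all significant pairs (each unordered pair enters B twice,
which leaves the mean unchanged by symmetry), and I_k = M_k * N_k — the
expected total link weight of the group's network.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .errors import ValidationError
from .network import AdjacencyMatrix, CorrelationMatrix


@dataclass(frozen=True)
class NodeIntensityRecord:
    node_id: int
    N: int
    M: float
    I: float
    rank: int


@dataclass(frozen=True)
class GroupIntensitySummary:
    N_k: int
    M_k: float
    I_k: float
    sum_I: float
    mean_I: float

    def to_dict(self) -> dict:
        return asdict(self)


def _check_aligned(c: CorrelationMatrix, b: AdjacencyMatrix) -> None:
    if not np.array_equal(c.band_ids, b.band_ids):
        raise ValidationError("correlation and adjacency band ids differ")


def node_intensity_table(
    c: CorrelationMatrix, b: AdjacencyMatrix
) -> list[NodeIntensityRecord]:
    """One record per node, ranked by descending I (ties: ascending id)."""
    _check_aligned(c, b)
    n_nodes = b.b.shape[0]
    N = b.b.sum(axis=1).astype(int)
    M = np.zeros(n_nodes)
    for i in range(n_nodes):
        if N[i]:
            M[i] = float(np.mean(c.r[i, b.b[i] == 1]))
    I = N * M
    order = np.lexsort((b.band_ids, -I))
    rank = np.empty(n_nodes, dtype=int)
    rank[order] = np.arange(1, n_nodes + 1)
    return [
        NodeIntensityRecord(
            node_id=int(b.band_ids[i]), N=int(N[i]), M=float(M[i]),
            I=float(I[i]), rank=int(rank[i]),
        )
        for i in range(n_nodes)
    ]


def intensity_frame(records: list[NodeIntensityRecord]) -> pd.DataFrame:
    """Records as a DataFrame with columns node, N, M, I, rank."""
    return pd.DataFrame(
        [(r.node_id, r.N, r.M, r.I, r.rank) for r in records],
        columns=["node", "N", "M", "I", "rank"],
    )


def group_intensity(
    c: CorrelationMatrix, b: AdjacencyMatrix
) -> GroupIntensitySummary:
    """Group-level N_k, M_k, I_k plus the sum and mean of per-node I."""
    _check_aligned(c, b)
    mask = b.b == 1
    N_k = int(mask.sum())
    M_k = float(np.mean(c.r[mask])) if N_k else 0.0
    records = node_intensity_table(c, b)
    sum_I = float(sum(r.I for r in records))
    return GroupIntensitySummary(
        N_k=N_k,
        M_k=M_k,
        I_k=M_k * N_k,
        sum_I=sum_I,
        mean_I=sum_I / len(records) if records else 0.0,
    )
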