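"""Link-loss (disconnection) comparison between two group networks.

Comparing adjacency a against adjacency b entrywise:

    (a=1, b=0) -> code 2  (link lost going from a to b)
    (a=0, b=1) -> code 1  (link gained)
    otherwise  -> code 0

The ledger collects, per node, the partners whose link carries code 2,
with nodes ordered by descending loss count (ties: ascending id).
Comparisons are ordered — "H vs BC" means links present in H's network
and absent in BC's.  Gains (code 1) are recorded alongside.

Two presentations exist.  The symmetric view lists every lost unordered
pair under both of its endpoints (so total list length = 2 x lost edges).
The published tables instead list each lost pair exactly once, under its
smaller-numbered endpoint; ``to_frame(style="upper")`` reproduces that
upper-triangle layout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .network import AdjacencyMatrix

LOST, GAINED, UNCHANGED = 2, 1, 0


def _check_same_ids(b_a: AdjacencyMatrix, b_b: AdjacencyMatrix) -> None:
    if not np.array_equal(b_a.band_ids, b_b.band_ids):
        raise ValidationError("adjacency matrices have different band ids")


def disconnection_codes(b_a: AdjacencyMatrix, b_b: AdjacencyMatrix) -> np.ndarray:
    """Entrywise comparison codes (2 lost, 1 gained, 0 unchanged)."""
    _check_same_ids(b_a, b_b)
    a, b = b_a.b, b_b.b
    return np.where((a == 1) & (b == 0), LOST, np.where((a == 0) & (b == 1), GAINED, UNCHANGED)).astype(np.int8)


@dataclass(frozen=True)
class DisconnectionLedger:
    """Per-node lost- and gained-link lists for an ordered group comparison."""

    comparison: tuple[str, str]
    band_ids: np.ndarray
    lost: dict[int, tuple[int, ...]]    # node -> sorted partners lost
    gained: dict[int, tuple[int, ...]]  # node -> sorted partners gained

    @property
    def total_lost_links(self) -> int:
        """Number of unique lost edges."""
        return sum(len(v) for v in self.lost.values()) // 2

    def count(self, node: int) -> int:
        return len(self.lost[node])

    def _ordered_nodes(self, table: dict[int, tuple[int, ...]]) -> list[int]:
        return sorted(table, key=lambda v: (-len(table[v]), v))

    def to_frame(self, style: str = "symmetric", what: str = "lost") -> pd.DataFrame:
        """Ledger as a table (node, n_lost, lost_partners).

        style="symmetric": each lost pair appears under both endpoints.
        style="upper": each lost pair appears once, under its smaller
        endpoint — the layout of the published disconnection tables.
        """
        if style not in ("symmetric", "upper"):
            raise ValidationError("style must be 'symmetric' or 'upper'")
        if what not in ("lost", "gained"):
            raise ValidationError("what must be 'lost' or 'gained'")
        table = self.lost if what == "lost" else self.gained
        if style == "upper":
            table = {n: tuple(p for p in v if p > n) for n, v in table.items()}
        rows = [
            (n, len(table[n]), ",".join(map(str, table[n])))
            for n in self._ordered_nodes(table)
        ]
        return pd.DataFrame(rows, columns=["node", f"n_{what}", f"{what}_partners"])


def disconnection_ledger(
    b_a: AdjacencyMatrix,
    b_b: AdjacencyMatrix,
    labels: tuple[str, str] = ("a", "b"),
) -> DisconnectionLedger:
    """Ledger of links present in ``b_a`` but absent in ``b_b`` (and gains)."""
    codes = disconnection_codes(b_a, b_b)
    ids = b_a.band_ids
    lost = {
        int(ids[i]): tuple(int(x) for x in ids[codes[i] == LOST])
        for i in range(ids.size)
    }
    gained = {
        int(ids[i]): tuple(int(x) for x in ids[codes[i] == GAINED])
        for i in range(ids.size)
    }
    return DisconnectionLedger(
        comparison=tuple(labels), band_ids=ids.copy(), lost=lost, gained=gained
    )


def write_ledger(ledger: DisconnectionLedger, path, style: str = "upper") -> None:
    ledger.to_frame(style=style).to_csv(path, sep="\t", index=False)
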