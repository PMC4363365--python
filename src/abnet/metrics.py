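"""Global network attributes and the degree-class histogram.

Conventions follow the published tables:

* ``n_links`` counts the ones in the symmetric adjacency B, i.e. each
  undirected edge twice (the sum of node degrees).
* ``density`` divides the *unique* edge count by n(n-1) — ordered node
  pairs — so a complete graph has density 0.5.  This is the convention that
  reproduces the printed per-group densities; the standard undirected
  density (twice this) is reported alongside as ``density_undirected``.
* ``degree_mean`` is n_links / n_nodes.
* ``diameter`` is the longest shortest path over *connected* node pairs;
  disconnected pairs are excluded and the component count is reported.
* the degree histogram uses the five published classes 2-6, 7-12, 13-18,
  19-24 and 25+, with nodes of degree < 2 reported as a remainder; nodes
  with at least ``hub_threshold`` (default 19) links count as hubs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict

import networkx as nx
import numpy as np

from .errors import UndefinedDiameterError, ValidationError
from .network import AdjacencyMatrix

logger = logging.getLogger(__name__)

DEGREE_CLASSES = ((2, 6), (7, 12), (13, 18), (19, 24), (25, None))
DEFAULT_HUB_THRESHOLD = 19


def link_count(b: AdjacencyMatrix) -> int:
    """Number of ones in B: each undirected edge counted twice."""
    return int(b.b.sum())


def density(b: AdjacencyMatrix) -> float:
    """Unique edges over n(n-1); complete graph -> 0.5."""
    n = b.b.shape[0]
    if n < 2:
        raise ValidationError("density needs at least 2 nodes")
    return link_count(b) / 2 / (n * (n - 1))


def density_undirected(b: AdjacencyMatrix) -> float:
    """Standard undirected density: unique edges over n(n-1)/2."""
    return 2.0 * density(b)


def degrees(b: AdjacencyMatrix) -> np.ndarray:
    """Per-node link counts (row sums of B), ordered as band_ids."""
    return b.b.sum(axis=1).astype(int)


def top_node(b: AdjacencyMatrix) -> int:
    """Band id with maximal degree; ties broken by smallest id."""
    d = degrees(b)
    order = np.lexsort((b.band_ids, -d))
    return int(b.band_ids[order[0]])


def n_components(b: AdjacencyMatrix) -> int:
    return nx.number_connected_components(b.to_graph())


def diameter(b: AdjacencyMatrix) -> int:
    """Max shortest-path length over connected node pairs, in links."""
    g = b.to_graph()
    if g.number_of_edges() == 0:
        raise UndefinedDiameterError("diameter undefined on an edgeless graph")
    comps = list(nx.connected_components(g))
    if len(comps) > 1:
        logger.info("diameter over %d components (disconnected pairs excluded)",
                    len(comps))
    return max(
        nx.diameter(g.subgraph(comp)) for comp in comps if len(comp) > 1
    )


@dataclass(frozen=True)
class NetworkSummary:
    """The per-group attribute table."""

    n_nodes: int
    n_links: int
    density: float
    density_undirected: float
    diameter: int | None
    top_node: int
    degree_min: int
    degree_max: int
    degree_mean: float
    degree_sd: float
    degree_var: float
    n_components: int

    def to_dict(self) -> dict:
        return asdict(self)


def summarize(b: AdjacencyMatrix) -> NetworkSummary:
    d = degrees(b)
    try:
        diam = diameter(b)
    except UndefinedDiameterError:
        diam = None
    # SD/variance with ddof=1, the reporting convention of common stats suites
    sd = float(d.std(ddof=1)) if d.size > 1 else 0.0
    return NetworkSummary(
        n_nodes=int(b.b.shape[0]),
        n_links=link_count(b),
        density=density(b),
        density_undirected=density_undirected(b),
        diameter=diam,
        top_node=top_node(b),
        degree_min=int(d.min()),
        degree_max=int(d.max()),
        degree_mean=link_count(b) / b.b.shape[0],
        degree_sd=sd,
        degree_var=sd * sd,
        n_components=n_components(b),
    )


@dataclass(frozen=True)
class DegreeHistogram:
    """Share of nodes per published degree class, in percent."""

    bins: tuple[tuple[int, int | None], ...]
    freq_percent: tuple[float, ...]
    remainder_percent: float
    hub_threshold: int
    hub_percent: float

    def to_dict(self) -> dict:
        labels = [
            f"{lo}-{hi}" if hi is not None else f"{lo}+" for lo, hi in self.bins
        ]
        return {
            "classes": labels,
            "freq_percent": list(self.freq_percent),
            "remainder_percent": self.remainder_percent,
            "hub_threshold": self.hub_threshold,
            "hub_percent": self.hub_percent,
        }


def degree_histogram(
    d: np.ndarray, hub_threshold: int = DEFAULT_HUB_THRESHOLD
) -> DegreeHistogram:
    d = np.asarray(d, dtype=int)
    n = d.size
    if n == 0:
        freq = tuple(0.0 for _ in DEGREE_CLASSES)
        return DegreeHistogram(DEGREE_CLASSES, freq, 0.0, hub_threshold, 0.0)
    freq = []
    for lo, hi in DEGREE_CLASSES:
        mask = d >= lo if hi is None else (d >= lo) & (d <= hi)
        freq.append(100.0 * mask.sum() / n)
    remainder = 100.0 * (d < DEGREE_CLASSES[0][0]).sum() / n
    hubs = 100.0 * (d >= hub_threshold).sum() / n
    return DegreeHistogram(
        bins=DEGREE_CLASSES,
        freq_percent=tuple(freq),
        remainder_percent=remainder,
        hub_threshold=hub_threshold,
        hub_percent=hubs,
    )
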