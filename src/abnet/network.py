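"""Pairwise band correlations, their significance, and the binary adjacency.

A link between two bands is a statistically significant Pearson correlation
between their 0/1 presence profiles across a group's sera.  On binary data
the Pearson coefficient coincides with the phi coefficient of the 2x2
contingency table.  Significance follows the t test of a correlation:

    t = r * sqrt(n - 2) / sqrt(1 - r^2),   df = n - 2,

with a two-tailed decision at level alpha — equivalently, one-tailed
p < alpha/2.  The correlation matrix R is binarized to the adjacency B by
b_ij = 1 exactly when the pair is significant (either sign), b_ii = 0.

No multiple-testing correction is applied by default: every pair is tested
at the raw alpha, which is what the published link counts require.
Bonferroni and Benjamini-Hochberg corrections are available behind a flag.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .band_matrix import BandMatrix
from .errors import UndefinedCorrelationError, ValidationError

logger = logging.getLogger(__name__)

CORRECTIONS = ("none", "bonferroni", "bh")


def pearson_binary(x, y) -> float:
    """Pearson coefficient of two equal-length binary vectors.

    Raises UndefinedCorrelationError when either vector has zero variance
    rather than letting a NaN propagate.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be equal-length 1-D vectors")
    if x.size < 3:
        raise ValidationError("need at least 3 observations")
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc @ xc) * (yc @ yc))
    if denom == 0.0:
        raise UndefinedCorrelationError("a vector has zero variance")
    return float(np.clip((xc @ yc) / denom, -1.0, 1.0))


@dataclass(frozen=True)
class CorrelationMatrix:
    """All pairwise Pearson coefficients of a band matrix.

    r : symmetric matrix, unit diagonal; NaN where undefined.
    defined : boolean mask, False for pairs involving a zero-variance band.
    n : sample size the coefficients were computed from.
    """

    r: np.ndarray
    defined: np.ndarray
    n: int
    band_ids: np.ndarray

    @property
    def n_undefined_bands(self) -> int:
        return int((~self.defined.any(axis=1)).sum())


def correlation_matrix(m: BandMatrix) -> CorrelationMatrix:
    """Pairwise coefficients among all bands; zero-variance bands are flagged
    undefined (their rows/columns are NaN) instead of raising."""
    if m.n < 3:
        raise ValidationError("need at least 3 participants")
    if m.n_bands < 2:
        raise ValidationError("need at least 2 bands")
    x = m.values.astype(float)
    variable = x.std(axis=0) > 0
    r = np.full((m.n_bands, m.n_bands), np.nan)
    if variable.sum() >= 2:
        sub = np.corrcoef(x[:, variable], rowvar=False)
        sub = (sub + sub.T) / 2.0  # corrcoef can be asymmetric in the last ulp
        r[np.ix_(variable, variable)] = np.clip(sub, -1.0, 1.0)
    elif variable.sum() == 1:
        i = int(np.flatnonzero(variable)[0])
        r[i, i] = 1.0
    defined = variable[:, None] & variable[None, :]
    n_const = int((~variable).sum())
    if n_const:
        logger.info("%d zero-variance band(s) flagged undefined", n_const)
    return CorrelationMatrix(r=r, defined=defined, n=m.n, band_ids=m.band_ids.copy())


def t_statistic(r, n: int):
    """The correlation t statistic; |r| = 1 maps to a signed infinity."""
    if n < 3:
        raise ValidationError("need n >= 3")
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r[np.isfinite(r)]) > 1):
        raise ValidationError("|r| must not exceed 1")
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
        t = np.where(np.abs(r) == 1.0, np.sign(r) * np.inf, t)
    return float(t) if t.ndim == 0 else t


def p_value(r, n: int):
    """Two-tailed p of the correlation t test (df = n - 2); 0 at |r| = 1."""
    t = t_statistic(r, n)
    t = np.asarray(t, dtype=float)
    p = np.where(np.isinf(t), 0.0, 2.0 * stats.t.sf(np.abs(t), n - 2))
    return float(p) if p.ndim == 0 else p


def critical_r(n: int, alpha: float = 0.05) -> float:
    """The |r| significance boundary: smallest magnitude declared significant
    at the two-tailed level alpha (approx. 0.2787 at n = 50, alpha = 0.05)."""
    _check_alpha(alpha)
    tc = stats.t.ppf(1.0 - alpha / 2.0, n - 2)
    return float(tc / np.sqrt(n - 2 + tc * tc))


@dataclass(frozen=True)
class SignificanceMatrix:
    """Test statistics and two-tailed p-values for every pair."""

    t: np.ndarray
    p: np.ndarray
    df: int


def significance_matrix(c: CorrelationMatrix) -> SignificanceMatrix:
    r_off = c.r.copy()
    np.fill_diagonal(r_off, np.nan)
    with np.errstate(invalid="ignore"):
        t = t_statistic(np.nan_to_num(r_off, nan=0.0), c.n)
        t = np.where(np.isnan(r_off), np.nan, t)
        p = np.where(
            np.isnan(r_off),
            np.nan,
            np.where(np.isinf(t), 0.0, 2.0 * stats.t.sf(np.abs(t), c.n - 2)),
        )
    return SignificanceMatrix(t=t, p=p, df=c.n - 2)


@dataclass(frozen=True)
class AdjacencyMatrix:
    """Symmetric 0/1 link matrix with zero diagonal.

    b_ij = 1 exactly when the pair's correlation (of either sign) is
    significant at ``alpha`` and both bands have nonzero variance.
    """

    b: np.ndarray
    alpha: float
    band_ids: np.ndarray
    correction: str = "none"

    def index_of(self, band_id: int) -> int:
        idx = np.flatnonzero(self.band_ids == band_id)
        if not idx.size:
            raise KeyError(f"band {band_id} not in adjacency")
        return int(idx[0])

    def to_graph(self, c: CorrelationMatrix | None = None) -> nx.Graph:
        """Undirected networkx graph; edge weight = r when ``c`` is given."""
        g = nx.Graph()
        g.add_nodes_from(int(b) for b in self.band_ids)
        ii, jj = np.nonzero(np.triu(self.b, 1))
        for i, j in zip(ii, jj):
            attrs = {}
            if c is not None:
                attrs["weight"] = float(c.r[i, j])
            g.add_edge(int(self.band_ids[i]), int(self.band_ids[j]), **attrs)
        return g


def _check_alpha(alpha: float) -> None:
    if not (0.0 < alpha < 1.0):
        raise ValidationError(f"alpha={alpha} outside (0, 1)")


def binarize(
    c: CorrelationMatrix, alpha: float = 0.05, correction: str = "none"
) -> AdjacencyMatrix:
    """Threshold a correlation matrix into the 0/1 adjacency B.

    Undefined pairs (zero-variance bands) get no links.  ``correction``
    optionally applies Bonferroni or Benjamini-Hochberg across the unique
    off-diagonal pairs; the default "none" matches the published analysis.
    """
    _check_alpha(alpha)
    if correction not in CORRECTIONS:
        raise ValidationError(f"correction must be one of {CORRECTIONS}")
    sig = significance_matrix(c)
    k = c.r.shape[0]
    iu = np.triu_indices(k, 1)
    p_upper = sig.p[iu]
    ok = ~np.isnan(p_upper)
    reject_upper = np.zeros(p_upper.size, dtype=bool)
    if ok.any():
        if correction == "none":
            reject_upper[ok] = p_upper[ok] < alpha
        else:
            from statsmodels.stats.multitest import multipletests
            method = {"bonferroni": "bonferroni", "bh": "fdr_bh"}[correction]
            reject_upper[ok] = multipletests(p_upper[ok], alpha=alpha, method=method)[0]
    b = np.zeros((k, k), dtype=np.int8)
    b[iu] = reject_upper
    b = b + b.T
    return AdjacencyMatrix(
        b=b, alpha=alpha, band_ids=c.band_ids.copy(), correction=correction
    )


def build_network(
    m: BandMatrix, alpha: float = 0.05, correction: str = "none"
) -> tuple[CorrelationMatrix, AdjacencyMatrix]:
    """Convenience: correlation matrix and adjacency in one call."""
    c = correlation_matrix(m)
    b = binarize(c, alpha=alpha, correction=correction)
    logger.info(
        "group=%s n=%d bands=%d links=%d (alpha=%g, correction=%s)",
        m.group, m.n, m.n_bands, int(b.b.sum()), alpha, correction,
    )
    return c, b


def edge_list(c: CorrelationMatrix, b: AdjacencyMatrix) -> pd.DataFrame:
    """Unique significant edges as (node_a, node_b, r, p), node_a < node_b."""
    sig = significance_matrix(c)
    ii, jj = np.nonzero(np.triu(b.b, 1))
    return pd.DataFrame(
        {
            "node_a": b.band_ids[ii],
            "node_b": b.band_ids[jj],
            "r": c.r[ii, jj],
            "p": sig.p[ii, jj],
        }
    )


def write_edge_list(c: CorrelationMatrix, b: AdjacencyMatrix, path: str | Path) -> None:
    edge_list(c, b).to_csv(path, sep="\t", index=False)


def write_graphml(c: CorrelationMatrix, b: AdjacencyMatrix, path: str | Path) -> None:
    nx.write_graphml(b.to_graph(c), str(path))
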