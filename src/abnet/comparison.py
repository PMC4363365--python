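"""Kruskal-Wallis comparison of per-node quantities across group networks.

The statistic is computed from its rank formula (with tie correction)
rather than delegated, so its behaviour on heavily tied integer data —
degrees are small integers — is pinned by the package's own tests:

    H = [ 12 / (N(N+1)) * sum_j R_j^2 / n_j - 3(N+1) ] / C,
    C = 1 - sum_t (t^3 - t) / (N^3 - N),

where R_j is the rank sum of group j over the pooled sample of size N and
t runs over tie-group sizes.  p is the upper tail of chi-square with
(number of groups - 1) degrees of freedom.  When all pooled values are
identical the statistic is defined as 0 with p = 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import ValidationError


@dataclass(frozen=True)
class GroupComparisonResult:
    statistic: float
    df: int
    p: float
    samples: tuple[str, ...]
    degenerate: bool = False

    def to_dict(self) -> dict:
        return {
            "statistic": self.statistic,
            "df": self.df,
            "p": self.p,
            "samples": list(self.samples),
            "degenerate": self.degenerate,
        }


def kruskal_wallis(
    samples: list[np.ndarray], labels: tuple[str, ...] | None = None
) -> GroupComparisonResult:
    """Rank-based H test that the groups share one distribution."""
    if len(samples) < 2:
        raise ValidationError("need at least two groups")
    samples = [np.asarray(s, dtype=float).ravel() for s in samples]
    if any(s.size == 0 for s in samples):
        raise ValidationError("every group must be nonempty")
    if labels is None:
        labels = tuple(f"group{i + 1}" for i in range(len(samples)))
    pooled = np.concatenate(samples)
    n_total = pooled.size
    df = len(samples) - 1
    if np.all(pooled == pooled[0]):
        return GroupComparisonResult(0.0, df, 1.0, tuple(labels), degenerate=True)
    ranks = stats.rankdata(pooled)  # average ranks for ties
    h = 0.0
    start = 0
    for s in samples:
        r_j = ranks[start : start + s.size].sum()
        h += r_j * r_j / s.size
        start += s.size
    h = 12.0 / (n_total * (n_total + 1)) * h - 3.0 * (n_total + 1)
    _, counts = np.unique(pooled, return_counts=True)
    correction = 1.0 - (counts**3 - counts).sum() / (n_total**3 - n_total)
    h /= correction
    return GroupComparisonResult(
        statistic=float(h),
        df=df,
        p=float(stats.chi2.sf(h, df)),
        samples=tuple(labels),
    )
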