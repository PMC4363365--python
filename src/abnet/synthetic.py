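"""Synthetic cohort generation via a Gaussian-copula threshold model.

The study's raw serum-by-band matrices were never deposited, so testable
inputs are simulated.  Each participant's band profile is obtained by
thresholding a latent multivariate-normal vector: bands belong to blocks
(stand-ins for sets of co-regulated IgG-producing clones), the latent
correlation is ``rho_within`` inside a block and ``rho_between`` across
blocks, and band ``j`` is scored present when its latent coordinate exceeds
the normal quantile matching its configured marginal prevalence.  This gives
a single dependence dial that works at any prevalence; note the realized
phi coefficient between two binary bands is attenuated relative to the
latent rho, so tests compare orderings and calibrations, not rho itself.

Default shape mirrors the study: 3 groups x 50 participants x 121 bands,
with per-band prevalences drawn uniformly from 0.10-0.60 (the study reports
no per-band prevalence; this range keeps bands informative but unsaturated).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

from .band_matrix import BandMatrix
from .errors import ConfigurationError

DEFAULT_N_PARTICIPANTS = 50
DEFAULT_N_BANDS = 121
DEFAULT_BLOCK_SIZE = 11
PREVALENCE_RANGE = (0.10, 0.60)


def default_blocks(n_bands: int, block_size: int = DEFAULT_BLOCK_SIZE) -> tuple[tuple[int, ...], ...]:
    """Partition band ids 1..n_bands into consecutive blocks of ~block_size."""
    ids = np.arange(1, n_bands + 1)
    return tuple(
        tuple(chunk) for chunk in np.array_split(ids, max(1, round(n_bands / block_size)))
    )


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of one synthetic cohort.

    prevalence may be a scalar (shared by all bands), a sequence of length
    n_bands, or None, in which case per-band prevalences are drawn uniformly
    from PREVALENCE_RANGE using ``seed`` (deterministically, and independently
    of the sampling noise stream).
    """

    n_participants: int = DEFAULT_N_PARTICIPANTS
    n_bands: int = DEFAULT_N_BANDS
    blocks: tuple[tuple[int, ...], ...] | None = None
    rho_within: float = 0.35
    rho_between: float = 0.05
    prevalence: float | tuple[float, ...] | None = None
    seed: int = 0
    group: str = "synthetic"

    def __post_init__(self) -> None:
        if self.n_participants < 1 or self.n_bands < 1:
            raise ConfigurationError("n_participants and n_bands must be positive")
        if not (0 <= self.rho_within < 1):
            raise ConfigurationError(f"rho_within={self.rho_within} outside [0, 1)")
        if not (0 <= self.rho_between <= self.rho_within):
            raise ConfigurationError(
                f"rho_between={self.rho_between} outside [0, rho_within={self.rho_within}]"
            )
        blocks = self.blocks
        if blocks is None:
            blocks = default_blocks(self.n_bands)
        blocks = tuple(tuple(int(b) for b in blk) for blk in blocks)
        flat = sorted(b for blk in blocks for b in blk)
        if flat != list(range(1, self.n_bands + 1)):
            raise ConfigurationError(
                f"blocks must partition band ids 1..{self.n_bands} exactly"
            )
        object.__setattr__(self, "blocks", blocks)
        if self.prevalence is not None and not np.isscalar(self.prevalence):
            object.__setattr__(self, "prevalence", tuple(float(p) for p in self.prevalence))
        pv = self.resolved_prevalence()
        if not ((pv > 0) & (pv < 1)).all():
            raise ConfigurationError("all prevalences must lie strictly inside (0, 1)")

    def resolved_prevalence(self) -> np.ndarray:
        """Per-band prevalence vector, drawing defaults deterministically."""
        if self.prevalence is None:
            rng = np.random.default_rng([int(self.seed), 0x5EED])
            lo, hi = PREVALENCE_RANGE
            return rng.uniform(lo, hi, size=self.n_bands)
        if np.isscalar(self.prevalence):
            return np.full(self.n_bands, float(self.prevalence))
        pv = np.asarray(self.prevalence, dtype=float)
        if pv.size != self.n_bands:
            raise ConfigurationError(
                f"prevalence has {pv.size} entries for {self.n_bands} bands"
            )
        return pv


def latent_correlation(config: SyntheticConfig) -> np.ndarray:
    """The block-structured latent correlation matrix implied by the config."""
    n = config.n_bands
    labels = np.empty(n, dtype=int)
    for k, blk in enumerate(config.blocks):
        labels[np.asarray(blk) - 1] = k
    same = labels[:, None] == labels[None, :]
    corr = np.where(same, config.rho_within, config.rho_between)
    np.fill_diagonal(corr, 1.0)
    return corr


def generate_cohort(config: SyntheticConfig) -> BandMatrix:
    """Sample one binary cohort from the copula model; reproducible by seed."""
    corr = latent_correlation(config)
    try:
        chol = np.linalg.cholesky(corr)
    except np.linalg.LinAlgError:
        raise ConfigurationError(
            "implied latent correlation matrix is not positive definite "
            f"(rho_within={config.rho_within}, rho_between={config.rho_between}, "
            f"{len(config.blocks)} blocks)"
        )
    rng = np.random.default_rng([int(config.seed), 0xC0F0])
    z = rng.standard_normal((config.n_participants, config.n_bands)) @ chol.T
    thresholds = stats.norm.ppf(1.0 - config.resolved_prevalence())
    values = (z > thresholds).astype(np.int8)
    return BandMatrix(
        values=values,
        band_ids=np.arange(1, config.n_bands + 1),
        participant_ids=tuple(
            f"{config.group}{i:03d}" for i in range(1, config.n_participants + 1)
        ),
        group=config.group,
    )


def group_scenario(
    intensity_order: tuple[str, ...],
    base: SyntheticConfig,
    scales: tuple[float, ...] | None = None,
) -> dict[str, SyntheticConfig]:
    """Per-group configs that induce the requested link-intensity ordering.

    Groups are listed from most to least connected; each gets the base config
    with rho_within (and rho_between, to preserve the rho_between <= rho_within
    contract) multiplied by a decreasing scale — default linearly spaced from
    1.0 down to 0.4, which for three groups gives factors (1.0, 0.7, 0.4).
    Prevalences are resolved once from the base config and shared, so groups
    differ only in dependence strength and noise stream.
    """
    groups = tuple(intensity_order)
    if len(groups) < 2:
        raise ConfigurationError("need at least two groups to order")
    if len(set(groups)) != len(groups):
        raise ConfigurationError("group labels must be distinct")
    if scales is None:
        scales = tuple(np.linspace(1.0, 0.4, len(groups)))
    if len(scales) != len(groups):
        raise ConfigurationError("one scale per group required")
    prevalence = tuple(base.resolved_prevalence())
    return {
        g: replace(
            base,
            group=g,
            prevalence=prevalence,
            rho_within=base.rho_within * s,
            rho_between=min(base.rho_between * s, base.rho_within * s),
            seed=int(base.seed) + i,
        )
        for i, (g, s) in enumerate(zip(groups, scales))
    }


def study_scenario(seed: int = 0, rho_within: float = 0.5) -> dict[str, SyntheticConfig]:
    """The default three-cohort scenario shaped like the study: 50 sera per
    group, 121 bands, dependence ordered BBP > H > BC."""
    base = SyntheticConfig(seed=seed, rho_within=rho_within)
    return group_scenario(("BBP", "H", "BC"), base)
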