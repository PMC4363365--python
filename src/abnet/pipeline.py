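"""End-to-end orchestration: cohorts in, tables/ledgers/exports out.

A run takes per-group band matrices (read from disk or simulated), builds
each group's significance-thresholded correlation network, and writes per
group: the edge list, a GraphML export, the attribute summary, the degree
histogram and the node-intensity table; per ordered group pair a
disconnection ledger; and across groups Kruskal-Wallis comparisons of the
per-node degree and intensity vectors.  A manifest records the
configuration, seed, library versions and the zero-variance band counts so
a run can be audited and reproduced.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from itertools import permutations
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .band_matrix import BandMatrix, load_fixture, read_band_matrix, write_band_matrix
from .comparison import kruskal_wallis
from .disconnection import disconnection_ledger, write_ledger
from .errors import ConfigurationError
from .intensity import group_intensity, intensity_frame, node_intensity_table
from .metrics import DEFAULT_HUB_THRESHOLD, degree_histogram, degrees, summarize
from .network import build_network, write_edge_list, write_graphml
from .synthetic import SyntheticConfig, generate_cohort

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Inputs and knobs of one pipeline run.

    Exactly one of ``inputs`` (group label -> band-matrix path) or
    ``scenario`` (group label -> SyntheticConfig) must be given.
    """

    output_dir: Path
    inputs: dict[str, Path] | None = None
    scenario: dict[str, SyntheticConfig] | None = None
    alpha: float = 0.05
    hub_threshold: int = DEFAULT_HUB_THRESHOLD
    correction: str = "none"
    seed: int = 0
    write_graphs: bool = True

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1):
            raise ConfigurationError(f"alpha={self.alpha} outside (0, 1)")
        if (self.inputs is None) == (self.scenario is None):
            raise ConfigurationError("give exactly one of inputs or scenario")


def _load_cohorts(config: PipelineConfig) -> dict[str, BandMatrix]:
    if config.inputs is not None:
        return {
            g: read_band_matrix(path, group=g) for g, path in config.inputs.items()
        }
    return {g: generate_cohort(sc) for g, sc in config.scenario.items()}


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, Path):
        return str(o)
    raise TypeError(type(o))


def _write_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=_json_default) + "\n")


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write the report bundle; returns the manifest."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "load-cohorts"
    try:
        cohorts = _load_cohorts(config)
        groups = list(cohorts)
        nets, summaries, zero_variance = {}, {}, {}
        for g, m in cohorts.items():
            stage = f"network[{g}]"
            c, b = build_network(m, alpha=config.alpha, correction=config.correction)
            nets[g] = (c, b)
            zero_variance[g] = c.n_undefined_bands
            if config.scenario is not None:
                write_band_matrix(m, out / f"{g}_band_matrix.tsv")

            stage = f"metrics[{g}]"
            summary = summarize(b)
            summaries[g] = summary
            hist = degree_histogram(degrees(b), hub_threshold=config.hub_threshold)
            _write_json(summary.to_dict(), out / f"{g}_summary.json")
            pd.DataFrame(
                {
                    "degree_class": hist.to_dict()["classes"] + ["<2"],
                    "freq_percent": list(hist.freq_percent) + [hist.remainder_percent],
                }
            ).to_csv(out / f"{g}_degree_histogram.tsv", sep="\t", index=False)

            stage = f"intensity[{g}]"
            records = node_intensity_table(c, b)
            intensity_frame(records).to_csv(
                out / f"{g}_intensity.tsv", sep="\t", index=False
            )
            _write_json(group_intensity(c, b).to_dict(), out / f"{g}_group_intensity.json")

            if config.write_graphs:
                stage = f"export[{g}]"
                write_edge_list(c, b, out / f"{g}_edges.tsv")
                write_graphml(c, b, out / f"{g}.graphml")
            logger.info(
                "group=%s shape=%dx%d links=%d zero-variance=%d",
                g, m.n, m.n_bands, summary.n_links, zero_variance[g],
            )

        stage = "disconnection"
        ledgers = {}
        for a, b_label in permutations(groups, 2):
            ledger = disconnection_ledger(
                nets[a][1], nets[b_label][1], labels=(a, b_label)
            )
            ledgers[(a, b_label)] = ledger
            write_ledger(ledger, out / f"disconnections_{a}_vs_{b_label}.tsv")

        stage = "comparison"
        comparisons = {}
        if len(groups) >= 2:
            deg_vectors = [degrees(nets[g][1]) for g in groups]
            comparisons["degree"] = kruskal_wallis(deg_vectors, tuple(groups)).to_dict()
            i_vectors = [
                intensity_frame(node_intensity_table(*nets[g]))["I"].to_numpy()
                for g in groups
            ]
            comparisons["intensity"] = kruskal_wallis(i_vectors, tuple(groups)).to_dict()
        else:
            logger.info("single group: across-group comparisons skipped")
        _write_json(comparisons, out / "comparisons.json")

        stage = "manifest"
        manifest = {
            "package_version": __version__,
            "numpy_version": np.__version__,
            "alpha": config.alpha,
            "correction": config.correction,
            "hub_threshold": config.hub_threshold,
            "seed": config.seed,
            "groups": groups,
            "inputs": {g: str(p) for g, p in config.inputs.items()}
            if config.inputs
            else None,
            "scenario": {
                g: {
                    "n_participants": sc.n_participants,
                    "n_bands": sc.n_bands,
                    "rho_within": sc.rho_within,
                    "rho_between": sc.rho_between,
                    "seed": sc.seed,
                }
                for g, sc in config.scenario.items()
            }
            if config.scenario
            else None,
            "links": {g: summaries[g].n_links for g in groups},
            "zero_variance_bands": zero_variance,
            "total_lost_links": {
                f"{a}_vs_{b}": lg.total_lost_links for (a, b), lg in ledgers.items()
            },
            "comparisons": comparisons,
        }
        _write_json(manifest, out / "manifest.json")
        return manifest
    except Exception as exc:
        raise type(exc)(f"pipeline stage {stage!r} failed: {exc}") from exc


# Table 2 cells that can be re-derived from the Table 3 fixture alone.
_CHECKED_CELLS = ("n_links", "degree_max", "top_node", "density_2dp")


def fixtures_check() -> pd.DataFrame:
    """Recompute Table-2-derivable cells from the Table 3 fixture and diff
    them against the Table 2 fixture.  Returns one row per (group, cell)
    with the printed and derived values and a match flag; all rows are
    expected to match."""
    fx = load_fixture()
    rows = []
    for g in ("H", "BBP", "BC"):
        t3 = fx.table3_group(g)
        n_nodes = len(t3)
        derived = {
            "n_links": int(t3["N"].sum()),
            "degree_max": int(t3["N"].max()),
            "top_node": int(t3["N"].idxmax()),
            "density_2dp": round(t3["N"].sum() / 2 / (n_nodes * (n_nodes - 1)), 2),
        }
        printed = {
            "n_links": int(fx.table2_value("Number of Links", g)),
            "degree_max": int(fx.table2_value("Maximum Node number", g)),
            "top_node": int(fx.table2_value("Node with more sociometric degree", g)),
            "density_2dp": fx.table2_value("Density", g),
        }
        for cell in _CHECKED_CELLS:
            rows.append(
                {
                    "group": g,
                    "cell": cell,
                    "printed": printed[cell],
                    "derived": derived[cell],
                    "match": printed[cell] == derived[cell],
                }
            )
    return pd.DataFrame(rows)
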