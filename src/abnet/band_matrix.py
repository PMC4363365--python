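"""Binary band-presence matrices and the packaged printed-table fixtures.

The raw input of the whole pipeline is a participants x bands matrix of 0/1
entries: one row per serum, one column per immunoblot band (a protein antigen
of distinct molecular weight), entry 1 when that serum's IgG antibodies
recognise the band.  Band ids are 1-based integers following the study's node
numbering; matrices are stored with columns in ascending band-id order.

The package also ships, as plain TSV fixtures, the published per-group network
summaries: global attributes (link counts, density, diameter, hubs), the
per-band N/M/I/rank table, and the inter-group disconnection ledgers.  These
are the reference values the analysis code is validated against.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ValidationError

GROUPS = ("H", "BBP", "BC")
#: Ordered group comparisons of the published disconnection ledgers.
COMPARISONS = (("H", "BC"), ("H", "BBP"), ("BBP", "BC"))


@dataclass(frozen=True)
class BandMatrix:
    """A validated binary participants x bands matrix for one cohort group.

    Parameters
    ----------
    values : ndarray of shape (n_participants, n_bands)
        Entries are exactly 0 or 1.
    band_ids : ndarray of int
        Unique band labels, ascending.
    participant_ids : tuple of str
        Unique row labels.
    group : str
        Cohort label; the study used H, BBP and BC but any label is accepted.
    """

    values: np.ndarray
    band_ids: np.ndarray
    participant_ids: tuple[str, ...]
    group: str = "unlabelled"

    def __post_init__(self) -> None:
        values = np.asarray(self.values)
        band_ids = np.asarray(self.band_ids, dtype=int)
        if values.ndim != 2:
            raise ValidationError("values must be a 2-D matrix")
        if values.shape[1] != band_ids.size:
            raise ValidationError(
                f"{values.shape[1]} columns but {band_ids.size} band ids"
            )
        if values.shape[0] != len(self.participant_ids):
            raise ValidationError(
                f"{values.shape[0]} rows but {len(self.participant_ids)} participant ids"
            )
        bad = np.argwhere((values != 0) & (values != 1))
        if bad.size:
            i, j = bad[0]
            raise ValidationError(
                f"non-binary entry {values[i, j]!r} at participant "
                f"{self.participant_ids[i]!r}, band {band_ids[j]}"
            )
        if np.unique(band_ids).size != band_ids.size:
            raise ValidationError("duplicate band ids")
        if len(set(self.participant_ids)) != len(self.participant_ids):
            raise ValidationError("duplicate participant ids")
        order = np.argsort(band_ids, kind="stable")
        object.__setattr__(self, "values", values[:, order].astype(np.int8))
        object.__setattr__(self, "band_ids", band_ids[order])
        object.__setattr__(self, "participant_ids", tuple(self.participant_ids))

    @property
    def n(self) -> int:
        """Number of participants (rows)."""
        return self.values.shape[0]

    @property
    def n_bands(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.participant_ids), columns=self.band_ids
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, BandMatrix):
            return NotImplemented
        return (
            self.group == other.group
            and self.participant_ids == other.participant_ids
            and np.array_equal(self.band_ids, other.band_ids)
            and np.array_equal(self.values, other.values)
        )


def _sniff_delimiter(header: str) -> str:
    try:
        return csv.Sniffer().sniff(header, delimiters=",\t;").delimiter
    except csv.Error:
        return "\t" if "\t" in header else ","


def read_band_matrix(path: str | Path, group: str = "unlabelled") -> BandMatrix:
    """Read a delimited band matrix: first column ``participant_id``, remaining
    column headers band ids, cells 0/1.  Comma vs tab is auto-detected."""
    path = Path(path)
    with open(path, newline="") as fh:
        header = fh.readline()
        if not header.strip():
            raise ValidationError(f"{path}: empty file")
        sep = _sniff_delimiter(header)
        names = [c.strip() for c in header.rstrip("\r\n").split(sep)]
        try:
            band_ids = [int(c) for c in names[1:]]
        except ValueError as exc:
            raise ValidationError(f"{path}: non-integer band id in header: {exc}")
        if len(set(band_ids)) != len(band_ids):
            dupes = sorted({b for b in band_ids if band_ids.count(b) > 1})
            raise ValidationError(f"{path}: duplicate band id(s) {dupes}")
        body = fh.read()
    df = pd.read_csv(
        io.StringIO(body), sep=sep, header=None, names=names, dtype={names[0]: str}
    )
    participant_ids = tuple(df.iloc[:, 0].astype(str)) if len(df) else ()
    values = df.iloc[:, 1:].to_numpy() if len(df) else np.empty((0, len(band_ids)))
    try:
        values = np.asarray(values, dtype=float)
    except (TypeError, ValueError) as exc:
        raise ValidationError(f"{path}: non-numeric cell: {exc}")
    if values.size and not np.isin(values, (0.0, 1.0)).all():
        i, j = np.argwhere(~np.isin(values, (0.0, 1.0)))[0]
        raise ValidationError(
            f"{path}: non-binary value {values[i, j]!r} at participant "
            f"{participant_ids[i]!r}, band {band_ids[j]}"
        )
    return BandMatrix(
        values=values.astype(np.int8).reshape(len(participant_ids), len(band_ids)),
        band_ids=np.asarray(band_ids, dtype=int),
        participant_ids=participant_ids,
        group=group,
    )


def write_band_matrix(m: BandMatrix, path: str | Path) -> None:
    """Write a band matrix; ``.csv`` suffix gives commas, anything else tabs."""
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = m.to_frame()
    df.index.name = "participant_id"
    df.to_csv(path, sep=sep)


# --------------------------------------------------------------------------
# Packaged fixtures of the published tables
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PrintedFixture:
    """The published reference tables, parsed.

    table2: global network attributes, one row per attribute, columns H/BBP/BC.
    table3: long-format per-band records (band, group, N, M, I, rank);
        exactly 121 bands per group.
    table4: disconnection ledgers (comparison, node, n_lost, lost_partners);
        partner lists are tuples of ints, kept verbatim as printed.
    """

    table2: pd.DataFrame = field(repr=False)
    table3: pd.DataFrame = field(repr=False)
    table4: pd.DataFrame = field(repr=False)

    def table2_value(self, attribute: str, group: str) -> float:
        row = self.table2.loc[self.table2["attribute"] == attribute, group]
        if row.empty:
            raise KeyError(attribute)
        return float(row.iloc[0])

    def table3_group(self, group: str) -> pd.DataFrame:
        sub = self.table3[self.table3["group"] == group]
        return sub.set_index("band").sort_index()

    def table4_comparison(self, a: str, b: str) -> pd.DataFrame:
        key = f"{a}_vs_{b}"
        sub = self.table4[self.table4["comparison"] == key]
        if sub.empty:
            raise KeyError(key)
        return sub.set_index("node")


def _fixture_path(name: str):
    ref = resources.files("abnet").joinpath("fixtures", name)
    if not ref.is_file():
        raise ConfigurationError(f"packaged fixture {name!r} is missing")
    return ref


def load_fixture(table: int | None = None) -> PrintedFixture:
    """Load the packaged printed tables.

    ``table`` (2, 3 or 4) is accepted for interface symmetry and validated;
    all three tables are cheap to parse, so the full fixture is returned
    either way.
    """
    if table is not None and table not in (2, 3, 4):
        raise ConfigurationError(f"no printed table {table}; choose 2, 3 or 4")
    with resources.as_file(_fixture_path("table2.tsv")) as p:
        t2 = pd.read_csv(p, sep="\t")
    with resources.as_file(_fixture_path("table3.tsv")) as p:
        t3 = pd.read_csv(p, sep="\t")
    with resources.as_file(_fixture_path("table4.tsv")) as p:
        t4 = pd.read_csv(p, sep="\t", keep_default_na=False)
    t4["lost_partners"] = [
        tuple(int(x) for x in str(s).split(",") if x) for s in t4["lost_partners"]
    ]
    if not all((t3["group"] == g).sum() == 121 for g in GROUPS):
        raise ConfigurationError("table3 fixture must have 121 band rows per group")
    if (t4["n_lost"] < 0).any():
        raise ConfigurationError("table4 fixture has a negative count")
    return PrintedFixture(table2=t2, table3=t3, table4=t4)
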