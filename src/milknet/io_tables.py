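"""Reading and writing feature tables, group metadata, and signed networks.

Feature tables follow the OTU-table convention: features (OTUs or
metabolites) as rows, samples as columns. A transposed dialect is handled
through an explicit orientation hint rather than guessed from the header.
Missing cells are hard errors — silently imputing zeros would corrupt
correlation estimates on the small sample sizes this kind of study has.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "FeatureTable",
    "GroupAssignment",
    "read_feature_table",
    "read_biom_json",
    "read_group_assignment",
    "write_group_assignment",
    "write_network",
    "read_network",
    "NETWORK_FORMATS",
]

NETWORK_FORMATS = ("graphml", "sif", "edge-tsv")

#: edge attributes every signed-network writer must preserve
EDGE_ATTRS = ("r", "p", "sign")


@dataclass
class FeatureTable:
    """A features x samples abundance matrix with validated labels.

    Parameters
    ----------
    data:
        DataFrame with feature identifiers as the index and sample
        identifiers as columns. Values must be finite and non-negative;
        counts for OTU tables, arbitrary non-negative abundances for
        metabolite tables.
    feature_kind:
        Either ``"otu"`` or ``"metabolite"``.
    """

    data: pd.DataFrame
    feature_kind: str = "otu"

    def __post_init__(self) -> None:
        if self.feature_kind not in ("otu", "metabolite"):
            raise ValueError(f"unknown feature_kind {self.feature_kind!r}")
        df = self.data
        if not isinstance(df, pd.DataFrame):
            raise TypeError("data must be a pandas DataFrame")
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate feature identifiers: {dups}")
        if df.columns.has_duplicates:
            dups = df.columns[df.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample identifiers: {dups}")
        values = df.to_numpy()
        if values.dtype == object or not np.issubdtype(values.dtype, np.number):
            raise ValueError("non-numeric values in feature table")
        if np.isnan(values).any():
            r, c = np.argwhere(np.isnan(values))[0]
            raise ValueError(
                f"missing value at feature {df.index[r]!r}, sample {df.columns[c]!r}; "
                "missing cells are errors, not zeros"
            )
        if np.isinf(values).any():
            raise ValueError("non-finite values in feature table")
        if (values < 0).any():
            r, c = np.argwhere(values < 0)[0]
            raise ValueError(
                f"negative value {values[r, c]} at feature {df.index[r]!r}, "
                f"sample {df.columns[c]!r}"
            )

    @property
    def feature_ids(self) -> list[str]:
        return [str(i) for i in self.data.index]

    @property
    def sample_ids(self) -> list[str]:
        return [str(c) for c in self.data.columns]

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def feature_totals(self) -> pd.Series:
        """Per-feature total abundance across samples."""
        return self.data.sum(axis=1)

    def subset_samples(self, sample_ids: Iterable[str]) -> "FeatureTable":
        sample_ids = list(sample_ids)
        missing = sorted(set(sample_ids) - set(self.sample_ids))
        if missing:
            raise KeyError(f"samples not in table: {missing}")
        return FeatureTable(self.data.loc[:, sample_ids], self.feature_kind)

    def subset_features(self, feature_ids: Iterable[str]) -> "FeatureTable":
        feature_ids = list(feature_ids)
        missing = sorted(set(feature_ids) - set(self.feature_ids))
        if missing:
            raise KeyError(f"features not in table: {missing}")
        return FeatureTable(self.data.loc[feature_ids, :], self.feature_kind)

    def to_tsv(self, path: str | Path) -> None:
        self.data.to_csv(path, sep="\t", index_label="#FeatureID")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FeatureTable):
            return NotImplemented
        return self.feature_kind == other.feature_kind and self.data.equals(other.data)


@dataclass
class GroupAssignment:
    """Mapping from sample identifier to treatment-group label."""

    mapping: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.mapping:
            raise ValueError("group assignment is empty")
        self.mapping = {str(k): str(v) for k, v in self.mapping.items()}

    def groups(self) -> dict[str, list[str]]:
        """Group label -> ordered list of member sample ids."""
        out: dict[str, list[str]] = {}
        for sample, group in self.mapping.items():
            out.setdefault(group, []).append(sample)
        return out

    def samples_in(self, group: str) -> list[str]:
        members = [s for s, g in self.mapping.items() if g == group]
        if not members:
            raise KeyError(f"group {group!r} is empty or unknown")
        return members

    def validate_against(self, *tables: FeatureTable) -> None:
        """Every assigned sample must exist in at least one loaded table."""
        known: set[str] = set()
        for t in tables:
            known.update(t.sample_ids)
        orphans = sorted(set(self.mapping) - known)
        if orphans:
            raise ValueError(f"samples assigned to groups but absent from all tables: {orphans}")

    def __getitem__(self, sample: str) -> str:
        return self.mapping[sample]

    def __iter__(self):
        return iter(self.mapping)

    def __len__(self) -> int:
        return len(self.mapping)


def read_feature_table(
    path: str | Path,
    orientation_hint: str = "features-as-rows",
    feature_kind: str = "otu",
) -> FeatureTable:
    """Read a tab-separated feature table.

    The canonical layout has one feature per row (first column = feature id,
    header = sample ids). Pass ``orientation_hint="samples-as-rows"`` for the
    transposed dialect; the result is identical to reading the untransposed
    file.
    """
    if orientation_hint not in ("features-as-rows", "samples-as-rows"):
        raise ValueError(f"unknown orientation_hint {orientation_hint!r}")
    df = pd.read_csv(path, sep="\t", index_col=0, comment=None)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    # locate non-numeric cells before coercion so the error can name them
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = df.index[bad.to_numpy().argmax()]
            raise ValueError(
                f"non-numeric value {df.loc[row, col]!r} at row {row!r}, column {col!r} in {path}"
            )
        df[col] = coerced
    if orientation_hint == "samples-as-rows":
        df = df.T
    return FeatureTable(df, feature_kind=feature_kind)


def read_biom_json(path: str | Path, feature_kind: str = "otu") -> FeatureTable:
    """Read a BIOM v1 (JSON dialect) table into a :class:`FeatureTable`.

    Supports both sparse and dense matrix encodings of the format.
    """
    with open(path) as fh:
        doc = json.load(fh)
    feature_ids = [row["id"] for row in doc["rows"]]
    sample_ids = [col["id"] for col in doc["columns"]]
    values = np.zeros((len(feature_ids), len(sample_ids)))
    if doc.get("matrix_type") == "sparse":
        for i, j, v in doc["data"]:
            values[int(i), int(j)] = v
    else:
        values[:] = np.asarray(doc["data"], dtype=float)
    df = pd.DataFrame(values, index=feature_ids, columns=sample_ids)
    return FeatureTable(df, feature_kind=feature_kind)


def read_group_assignment(path: str | Path) -> GroupAssignment:
    """Read two-column TSV metadata (sample_id, group)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"group metadata {path} needs two columns (sample_id, group)")
    sample_col, group_col = df.columns[:2]
    if df[sample_col].duplicated().any():
        dups = df.loc[df[sample_col].duplicated(), sample_col].tolist()
        raise ValueError(f"duplicate sample ids in group metadata: {dups}")
    return GroupAssignment(dict(zip(df[sample_col], df[group_col])))


def write_group_assignment(groups: GroupAssignment, path: str | Path) -> None:
    pd.DataFrame(
        {"sample_id": list(groups.mapping), "group": list(groups.mapping.values())}
    ).to_csv(path, sep="\t", index=False)


def _check_signed(net: nx.Graph) -> None:
    for a, b, attrs in net.edges(data=True):
        for key in EDGE_ATTRS:
            if key not in attrs:
                raise ValueError(f"edge ({a!r}, {b!r}) lacks attribute {key!r}")


def write_network(net: nx.Graph, path: str | Path, format: str = "graphml") -> None:
    """Write a signed network in a Cytoscape-consumable format.

    ``graphml`` and ``edge-tsv`` preserve the ``r``, ``p`` and ``sign`` edge
    attributes at full precision; ``sif`` encodes only the sign, as the
    interaction-type token (``pos``/``neg``).
    """
    if format not in NETWORK_FORMATS:
        raise ValueError(f"unknown network format {format!r}; choose from {NETWORK_FORMATS}")
    _check_signed(net)
    path = Path(path)
    if format == "graphml":
        nx.write_graphml(net, path)
    elif format == "sif":
        with open(path, "w") as fh:
            written = set()
            for a, b, attrs in net.edges(data=True):
                fh.write(f"{a}\t{attrs['sign']}\t{b}\n")
                written.update((a, b))
            for node in net.nodes:
                if node not in written:
                    fh.write(f"{node}\n")
    else:  # edge-tsv
        rows = [
            {
                "source": a,
                "target": b,
                "r": repr(float(attrs["r"])),
                "p": repr(float(attrs["p"])),
                "sign": attrs["sign"],
            }
            for a, b, attrs in net.edges(data=True)
        ]
        pd.DataFrame(rows, columns=["source", "target", "r", "p", "sign"]).to_csv(
            path, sep="\t", index=False
        )


def read_network(path: str | Path, format: str = "graphml") -> nx.Graph:
    """Read a network written by :func:`write_network` (graphml or edge-tsv)."""
    if format == "graphml":
        g = nx.read_graphml(path)
        return nx.Graph(g)
    if format == "edge-tsv":
        df = pd.read_csv(path, sep="\t", dtype={"source": str, "target": str})
        g = nx.Graph()
        for row in df.itertuples(index=False):
            g.add_edge(row.source, row.target, r=float(row.r), p=float(row.p), sign=row.sign)
        return g
    raise ValueError(f"cannot read format {format!r}; use graphml or edge-tsv")
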