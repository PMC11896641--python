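"""Readers and writers for the plain-text formats used across the pipeline.

Feature tables are tab-separated (QIIME2 ``feature-table`` export dialect:
a leading ``# Constructed from biom file`` comment and an ``#OTU ID`` header
cell are tolerated), metadata is QIIME2 sample-metadata style TSV, networks
round-trip through GraphML or an edge-list TSV.

The in-memory conventions are:

* abundance table — :class:`pandas.DataFrame` of non-negative integers,
  features as rows, samples as columns;
* metadata — :class:`pandas.DataFrame` indexed by sample id with at least
  ``habitat``, ``stand_age`` and ``plot`` columns (all kept as strings);
* annotation map — :class:`pandas.Series` feature/taxon id -> label.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger("microstand")

REQUIRED_METADATA_COLUMNS = ("habitat", "stand_age", "plot")

#: header spellings accepted for the sample-id column of a metadata file
_SAMPLE_ID_ALIASES = {"sample_id", "#sampleid", "sample-id", "sampleid", "#sample id"}


class FormatError(ValueError):
    """Raised when an input file violates the format contract."""


def _strip_preamble(lines: list[str]) -> list[str]:
    """Drop leading comment lines that are not themselves the header row.

    The QIIME2 TSV export starts with ``# Constructed from biom file``
    followed by the real header ``#OTU ID\\t...``; only comment lines
    without a tab are treated as preamble.
    """
    out = list(lines)
    while out and out[0].startswith("#") and "\t" not in out[0]:
        out.pop(0)
    return out


def read_abundance_table(path, orientation: str = "features_as_rows") -> pd.DataFrame:
    """Read and validate an integer feature table from TSV.

    Parameters
    ----------
    path
        TSV file; first column holds IDs, remaining cells counts.
    orientation
        ``"features_as_rows"`` (default) or ``"samples_as_rows"``; the
        returned frame is always features x samples.

    Raises
    ------
    FormatError
        On duplicate IDs, negative, non-numeric or non-integer cells
        (non-integer cells are rejected, never rounded); the message
        names the offending row and column.
    """
    if orientation not in ("features_as_rows", "samples_as_rows"):
        raise ValueError(f"unknown orientation: {orientation!r}")
    text = Path(path).read_text()
    lines = _strip_preamble(text.splitlines())
    if not lines:
        raise FormatError(f"{path}: empty file")
    from io import StringIO

    df = pd.read_csv(StringIO("\n".join(lines)), sep="\t", index_col=0, dtype=str)
    df.index = df.index.astype(str)
    df.index.name = "feature_id"
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise FormatError(f"{path}: duplicate row IDs {dups}")
    if df.columns.duplicated().any():
        dups = df.columns[df.columns.duplicated()].unique().tolist()
        raise FormatError(f"{path}: duplicate column IDs {dups}")
    values = np.empty(df.shape, dtype=float)
    for j, col in enumerate(df.columns):
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna()
        if bad.any():
            row = df.index[bad.to_numpy().argmax()]
            raise FormatError(f"{path}: non-numeric cell at row {row!r}, column {col!r}")
        values[:, j] = converted.to_numpy()
    if (values < 0).any():
        i, j = np.argwhere(values < 0)[0]
        raise FormatError(
            f"{path}: negative cell at row {df.index[i]!r}, column {df.columns[j]!r}"
        )
    frac = values != np.floor(values)
    if frac.any():
        i, j = np.argwhere(frac)[0]
        raise FormatError(
            f"{path}: non-integer cell {values[i, j]!r} at row {df.index[i]!r}, "
            f"column {df.columns[j]!r} (counts must be whole numbers)"
        )
    table = pd.DataFrame(values.astype(np.int64), index=df.index, columns=df.columns)
    if orientation == "samples_as_rows":
        table = table.T
        table.index.name = "feature_id"
    return table


def write_abundance_table(table: pd.DataFrame, path, qiime_header: bool = False) -> None:
    """Write a feature table as TSV (features as rows)."""
    out = table.copy()
    if qiime_header:
        out.index.name = "#OTU ID"
    out.to_csv(path, sep="\t")


def read_metadata(path) -> pd.DataFrame:
    """Read sample metadata; returns a frame indexed by sample id.

    ``stand_age`` is kept as a categorical string label, never a number —
    ages are factor levels in every downstream test. Extra columns are
    preserved untouched.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    first = df.columns[0]
    if first.lower() in _SAMPLE_ID_ALIASES:
        df = df.rename(columns={first: "sample_id"})
    if "sample_id" not in df.columns:
        raise FormatError(f"{path}: no sample_id column (first column was {first!r})")
    missing = [c for c in REQUIRED_METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    if df["sample_id"].duplicated().any():
        dups = df["sample_id"][df["sample_id"].duplicated()].tolist()
        raise FormatError(f"{path}: duplicate sample_id {dups}")
    return df.set_index("sample_id")


def write_metadata(metadata: pd.DataFrame, path) -> None:
    metadata.to_csv(path, sep="\t", index_label="sample_id")


def align_metadata(table: pd.DataFrame, metadata: pd.DataFrame) -> pd.DataFrame:
    """Return metadata reindexed to the table's samples.

    Raises :class:`FormatError` listing every sample present in the table
    but absent from the metadata.
    """
    orphans = [s for s in table.columns if s not in metadata.index]
    if orphans:
        raise FormatError(f"samples missing from metadata: {orphans}")
    return metadata.loc[list(table.columns)]


def read_annotation_map(path, column: str | None = None) -> pd.Series:
    """Read a feature/taxon -> annotation map from TSV.

    The first column is the key; ``column`` selects the annotation column
    by name (default: the second column). Duplicate keys with conflicting
    labels are an error — each feature maps to at most one annotation.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: annotation map needs at least two columns")
    key = df.columns[0]
    col = column if column is not None else df.columns[1]
    if col not in df.columns:
        raise FormatError(f"{path}: no annotation column {col!r}")
    sub = df[[key, col]].dropna()
    conflict = sub.groupby(key)[col].nunique()
    if (conflict > 1).any():
        bad = conflict[conflict > 1].index.tolist()
        raise FormatError(f"{path}: conflicting annotations for {bad}")
    return sub.drop_duplicates(key).set_index(key)[col]


# ---------------------------------------------------------------------------
# distance matrices
# ---------------------------------------------------------------------------

def write_distance_matrix(dm: pd.DataFrame, path) -> None:
    dm.to_csv(path, sep="\t", index_label="sample_id")


def read_distance_matrix(path) -> pd.DataFrame:
    dm = pd.read_csv(path, sep="\t", index_col=0)
    dm.columns = dm.columns.astype(str)
    dm.index = dm.index.astype(str)
    if list(dm.index) != list(dm.columns):
        raise FormatError(f"{path}: row and column sample IDs differ")
    return dm


# ---------------------------------------------------------------------------
# networks
# ---------------------------------------------------------------------------

def write_network(net: nx.Graph, path, format: str = "graphml") -> None:
    """Write a co-occurrence network.

    ``graphml`` carries every node/edge/graph attribute; ``edgelist_tsv``
    writes the columns ``source  target  rho  sign  q_value``.
    """
    if format == "graphml":
        nx.write_graphml(net, path)
    elif format == "edgelist_tsv":
        rows = [
            {
                "source": u,
                "target": v,
                "rho": d["rho"],
                "sign": d["sign"],
                "q_value": d["q_value"],
            }
            for u, v, d in net.edges(data=True)
        ]
        pd.DataFrame(rows, columns=["source", "target", "rho", "sign", "q_value"]).to_csv(
            path, sep="\t", index=False
        )
    else:
        raise ValueError(f"unknown network format: {format!r}")


def read_network(path, format: str = "graphml") -> nx.Graph:
    if format == "graphml":
        return nx.read_graphml(path)
    if format == "edgelist_tsv":
        df = pd.read_csv(path, sep="\t", dtype={"source": str, "target": str})
        g = nx.Graph()
        for rec in df.itertuples(index=False):
            g.add_edge(rec.source, rec.target, rho=float(rec.rho), sign=rec.sign,
                       q_value=float(rec.q_value))
        return g
    raise ValueError(f"unknown network format: {format!r}")


def write_run_log(path, command: str, params: dict) -> None:
    """Sidecar JSON run log capturing the exact parameters of a CLI call."""
    payload = {"command": command, "params": params}
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True, default=str) + "\n")
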