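"""Readers and writers for the plain-text formats the pipeline touches.

Feature tables and metadata are tab-separated; trees are newick; distance
matrices are labeled square TSV (the ``lsmat`` convention scikit-bio uses);
alignments are FASTA. All parsers fail loudly with location information
rather than silently dropping rows.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import skbio
from skbio import DistanceMatrix, TreeNode

from phylosym.datamodel import (
    AlignedSequences,
    FeatureTable,
    FormatError,
    SampleMetadata,
    SchemaError,
    metadata_frame,
    validate_tree,
)

logger = logging.getLogger(__name__)

REQUIRED_METADATA_COLUMNS = (
    "sample_id", "population", "species", "latitude", "longitude",
    "altitude", "host_plant",
)

__all__ = [
    "read_feature_table", "write_feature_table",
    "read_newick", "write_newick",
    "read_metadata", "write_metadata",
    "read_distance_matrix", "write_distance_matrix",
    "read_alignment",
]


# ---------------------------------------------------------------- tables
def read_feature_table(path: str | Path, dialect: str = "tsv") -> FeatureTable:
    """Read a count table.

    ``tsv``: samples as rows, first column sample ids, header of taxon ids.
    ``biom_dense``: the dense BIOM TSV convention — taxa as rows under an
    ``#OTU ID`` header (optionally preceded by a ``# Constructed from ...``
    comment), samples as columns; transposed on read.
    """
    path = Path(path)
    if dialect not in ("tsv", "biom_dense"):
        raise ValueError(f"unknown dialect {dialect!r}")
    skiprows = 0
    if dialect == "biom_dense":
        with open(path) as fh:
            first = fh.readline()
        if first.startswith("#") and not first.startswith("#OTU"):
            skiprows = 1
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, skiprows=skiprows)
    except Exception as exc:  # noqa: BLE001 - rewrap with file context
        raise FormatError(f"{path}: cannot parse as {dialect}: {exc}") from exc
    if dialect == "biom_dense":
        df = df.T
    df.index = df.index.map(str)
    df.columns = df.columns.map(str)
    arr = df.to_numpy()
    if arr.dtype == object or not np.issubdtype(arr.dtype, np.number):
        for j, col in enumerate(df.columns):
            coerced = pd.to_numeric(df[col], errors="coerce")
            if coerced.isna().any():
                row = df.index[coerced.isna().to_numpy().argmax()]
                raise FormatError(
                    f"{path}: non-numeric count at row {row!r}, column {col!r}")
        df = df.apply(pd.to_numeric)
    try:
        return FeatureTable.from_dataframe(df)
    except FormatError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_feature_table(table: FeatureTable, path: str | Path,
                        dialect: str = "tsv") -> None:
    df = table.to_dataframe()
    if dialect == "biom_dense":
        df = df.T
        df.index.name = "#OTU ID"
    else:
        df.index.name = "sample_id"
    df.to_csv(path, sep="\t")


# ----------------------------------------------------------------- trees
def read_newick(path_or_str: str | Path) -> TreeNode:
    """Parse a newick tree; missing branch lengths become 0 (warned)."""
    if isinstance(path_or_str, Path) or Path(str(path_or_str)).exists():
        text = Path(path_or_str).read_text().strip()
    else:
        text = str(path_or_str).strip()
    depth = 0
    for offset, ch in enumerate(text):
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                raise FormatError(
                    f"unbalanced ')' at character offset {offset}")
    if depth != 0:
        raise FormatError(
            f"unbalanced '(': {depth} unclosed at end of string "
            f"(length {len(text)})")
    try:
        tree = TreeNode.read([text])
    except Exception as exc:  # noqa: BLE001
        raise FormatError(f"newick parse error: {exc}") from exc
    n_missing = 0
    for node in tree.traverse(include_self=False):
        if node.length is None:
            node.length = 0.0
            n_missing += 1
    if n_missing:
        logger.warning("newick input: %d missing branch lengths set to 0",
                       n_missing)
    return validate_tree(tree)


def write_newick(tree: TreeNode, path: str | Path) -> None:
    tree.write(str(path), format="newick")


# -------------------------------------------------------------- metadata
def read_metadata(path: str | Path) -> list[SampleMetadata]:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in REQUIRED_METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns: {missing}")
    records: list[SampleMetadata] = []
    aux_cols = [c for c in df.columns
                if c not in REQUIRED_METADATA_COLUMNS + ("collection_year",)]
    for i, row in df.iterrows():
        rownum = i + 2  # header is line 1
        numeric = {}
        for col in ("latitude", "longitude", "altitude"):
            try:
                numeric[col] = float(row[col])
            except (TypeError, ValueError) as exc:
                raise SchemaError(
                    f"{path}: row {rownum}: cannot parse {col}={row[col]!r}"
                ) from exc
        year = None
        if "collection_year" in df.columns and pd.notna(row.get("collection_year")):
            year = int(float(row["collection_year"]))
        try:
            records.append(SampleMetadata(
                sample_id=str(row["sample_id"]),
                population=str(row["population"]),
                species=str(row["species"]),
                latitude=numeric["latitude"],
                longitude=numeric["longitude"],
                altitude=numeric["altitude"],
                host_plant=str(row["host_plant"]),
                collection_year=year,
                extra={c: row[c] for c in aux_cols if pd.notna(row[c])},
            ))
        except SchemaError as exc:
            raise SchemaError(f"{path}: row {rownum}: {exc}") from exc
    ids = [r.sample_id for r in records]
    if len(set(ids)) != len(ids):
        raise SchemaError(f"{path}: duplicate sample_id values")
    return records


def write_metadata(records: Sequence[SampleMetadata], path: str | Path) -> None:
    metadata_frame(records).to_csv(path, sep="\t")


# ------------------------------------------------------- distance matrix
def read_distance_matrix(dm_path: str | Path,
                         labels: Sequence[str] | None = None) -> DistanceMatrix:
    """Read a labeled square TSV distance matrix.

    Asymmetries up to 1e-8 are symmetrized; larger ones are errors, as is a
    nonzero diagonal. ``labels`` optionally reorders the result.
    """
    df = pd.read_csv(dm_path, sep="\t", index_col=0)
    df.index = df.index.map(str)
    df.columns = df.columns.map(str)
    if list(df.index) != list(df.columns):
        raise FormatError(f"{dm_path}: row and column labels differ")
    vals = df.to_numpy(dtype=float)
    asym = np.abs(vals - vals.T).max() if vals.size else 0.0
    if asym > 1e-8:
        raise FormatError(
            f"{dm_path}: matrix asymmetric (max |a-b| = {asym:.3g})")
    if vals.size and np.abs(np.diag(vals)).max() > 1e-12:
        raise FormatError(f"{dm_path}: nonzero diagonal")
    vals = (vals + vals.T) / 2.0
    np.fill_diagonal(vals, 0.0)
    dm = DistanceMatrix(vals, ids=list(df.index))
    if labels is not None:
        dm = dm.filter(list(labels))
    return dm


def write_distance_matrix(dm: DistanceMatrix, path: str | Path) -> None:
    pd.DataFrame(dm.data, index=list(dm.ids), columns=list(dm.ids)).to_csv(
        path, sep="\t", float_format="%.17g")


# ------------------------------------------------------------- alignment
def read_alignment(path: str | Path) -> AlignedSequences:
    labels, seqs = [], []
    for seq in skbio.io.read(str(path), format="fasta"):
        labels.append(seq.metadata["id"])
        seqs.append(str(seq))
    if not labels:
        raise FormatError(f"{path}: empty FASTA")
    return AlignedSequences(tuple(labels), tuple(seqs))
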