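"""Core domain types shared across the analysis chain.

Trees are represented as :class:`skbio.TreeNode` and pairwise
dissimilarities as :class:`skbio.DistanceMatrix`; this module adds the
amplicon-specific containers (feature table, per-sample metadata, aligned
host sequences) plus validation helpers.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode

__all__ = [
    "FeatureTable",
    "SampleMetadata",
    "AlignedSequences",
    "FormatError",
    "SchemaError",
    "validate_tree",
    "metadata_frame",
]


class FormatError(ValueError):
    """A file or in-memory object violates a structural invariant."""


class SchemaError(ValueError):
    """A tabular input is missing required columns or has bad types."""


def _check_unique(labels: Sequence[str], what: str) -> tuple[str, ...]:
    labels = tuple(str(x) for x in labels)
    if len(set(labels)) != len(labels):
        seen, dups = set(), []
        for x in labels:
            if x in seen:
                dups.append(x)
            seen.add(x)
        raise FormatError(f"duplicate {what} identifiers: {sorted(set(dups))}")
    return labels


@dataclass(frozen=True)
class FeatureTable:
    """Samples × taxa matrix of non-negative integer read counts.

    Rows are samples, columns are taxa (ASVs). The central observational
    object: every downstream stage (rarefaction, diversity, networks)
    consumes one of these.
    """

    sample_ids: tuple[str, ...]
    taxon_ids: tuple[str, ...]
    counts: np.ndarray

    def __post_init__(self) -> None:
        sample_ids = _check_unique(self.sample_ids, "sample")
        taxon_ids = _check_unique(self.taxon_ids, "taxon")
        counts = np.asarray(self.counts)
        if counts.shape != (len(sample_ids), len(taxon_ids)):
            raise FormatError(
                f"counts shape {counts.shape} does not match "
                f"{len(sample_ids)} samples × {len(taxon_ids)} taxa"
            )
        if not np.issubdtype(counts.dtype, np.integer):
            rounded = np.rint(counts)
            if not np.allclose(counts, rounded, rtol=0, atol=1e-9):
                bad = np.argwhere(np.abs(counts - rounded) > 1e-9)[0]
                raise FormatError(
                    f"non-integer count {counts[tuple(bad)]!r} at sample "
                    f"{sample_ids[bad[0]]!r}, taxon {taxon_ids[bad[1]]!r}"
                )
            counts = rounded.astype(np.int64)
        if (counts < 0).any():
            i, j = np.argwhere(counts < 0)[0]
            raise FormatError(
                f"negative count at sample {sample_ids[i]!r}, taxon {taxon_ids[j]!r}"
            )
        object.__setattr__(self, "sample_ids", sample_ids)
        object.__setattr__(self, "taxon_ids", taxon_ids)
        object.__setattr__(self, "counts", counts)

    # -- basic geometry -------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def sample_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def relative_abundance(self) -> np.ndarray:
        """Row-normalized counts; rows with zero total stay all-zero."""
        totals = self.sample_totals().astype(float)
        out = np.zeros(self.counts.shape, dtype=float)
        pos = totals > 0
        out[pos] = self.counts[pos] / totals[pos, None]
        return out

    # -- construction / conversion --------------------------------------
    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "FeatureTable":
        return cls(tuple(map(str, df.index)), tuple(map(str, df.columns)),
                   df.to_numpy())

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.sample_ids),
                            columns=list(self.taxon_ids))

    # -- subsetting ------------------------------------------------------
    def filter_samples(self, keep: Iterable[str]) -> "FeatureTable":
        keep = list(keep)
        idx = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in keep if s not in idx]
        if missing:
            raise KeyError(f"samples not in table: {missing}")
        rows = [idx[s] for s in keep]
        return FeatureTable(tuple(keep), self.taxon_ids, self.counts[rows])

    def filter_taxa(self, keep: Iterable[str]) -> "FeatureTable":
        keep = list(keep)
        idx = {t: j for j, t in enumerate(self.taxon_ids)}
        missing = [t for t in keep if t not in idx]
        if missing:
            raise KeyError(f"taxa not in table: {missing}")
        cols = [idx[t] for t in keep]
        return FeatureTable(self.sample_ids, tuple(keep), self.counts[:, cols])

    def drop_empty_taxa(self) -> "FeatureTable":
        keep = [t for t, tot in zip(self.taxon_ids, self.counts.sum(axis=0))
                if tot > 0]
        return self.filter_taxa(keep)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FeatureTable):
            return NotImplemented
        return (self.sample_ids == other.sample_ids
                and self.taxon_ids == other.taxon_ids
                and np.array_equal(self.counts, other.counts))


@dataclass(frozen=True)
class SampleMetadata:
    """One sampling record: where the host came from and what it eats."""

    sample_id: str
    population: str
    species: str
    latitude: float
    longitude: float
    altitude: float
    host_plant: str
    collection_year: int | None = None
    extra: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not -90.0 <= self.latitude <= 90.0:
            raise SchemaError(
                f"latitude {self.latitude} out of [-90, 90] for sample "
                f"{self.sample_id!r}")
        if not -180.0 <= self.longitude <= 180.0:
            raise SchemaError(
                f"longitude {self.longitude} out of [-180, 180] for sample "
                f"{self.sample_id!r}")


def metadata_frame(records: Sequence[SampleMetadata]) -> pd.DataFrame:
    """Tabulate metadata records, sample_id as the index."""
    rows = []
    for r in records:
        d = {
            "sample_id": r.sample_id,
            "population": r.population,
            "species": r.species,
            "latitude": r.latitude,
            "longitude": r.longitude,
            "altitude": r.altitude,
            "host_plant": r.host_plant,
        }
        if r.collection_year is not None:
            d["collection_year"] = r.collection_year
        d.update(r.extra)
        rows.append(d)
    return pd.DataFrame(rows).set_index("sample_id")


@dataclass(frozen=True)
class AlignedSequences:
    """A multiple sequence alignment over {A, C, G, T, -, N}."""

    labels: tuple[str, ...]
    sequences: tuple[str, ...]

    def __post_init__(self) -> None:
        labels = _check_unique(self.labels, "sequence")
        seqs = tuple(s.upper() for s in self.sequences)
        if len(labels) != len(seqs):
            raise FormatError("labels and sequences differ in length")
        lengths = {len(s) for s in seqs}
        if len(lengths) > 1:
            raise FormatError(f"unequal alignment lengths: {sorted(lengths)}")
        allowed = set("ACGT-N")
        for lab, s in zip(labels, seqs):
            bad = set(s) - allowed
            if bad:
                raise FormatError(
                    f"sequence {lab!r} contains invalid symbols {sorted(bad)}")
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "sequences", seqs)

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def alignment_length(self) -> int:
        return len(self.sequences[0]) if self.sequences else 0


def validate_tree(tree: TreeNode, require_branch_lengths: bool = False) -> TreeNode:
    """Check leaf-label uniqueness and non-negative branch lengths."""
    tips = [t.name for t in tree.tips()]
    _check_unique(tips, "leaf")
    for node in tree.traverse(include_self=False):
        if node.length is not None and node.length < 0:
            raise FormatError(
                f"negative branch length {node.length} at node {node.name!r}")
        if require_branch_lengths and node.length is None:
            raise FormatError(f"missing branch length at node {node.name!r}")
    return tree
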