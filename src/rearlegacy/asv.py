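"""The ASV count table container.

An :class:`AsvTable` holds a non-negative integer matrix of samples x ASVs
(amplicon sequence variants, i.e. exact 16S sequence units) together with
per-sample metadata (rearing system, diet, timepoint, tank, fish).  It is a
thin, validated wrapper around two aligned pandas DataFrames; community
statistics operate on it.
"""

from __future__ import annotations

from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = ["AsvTable"]


class AsvTable:
    """Samples x ASVs count matrix with aligned sample metadata.

    Parameters
    ----------
    counts : pandas.DataFrame
        Rows are samples, columns are ASVs; entries are non-negative integers.
    metadata : pandas.DataFrame, optional
        Indexed like ``counts`` (one row per sample).  Typical columns:
        ``system`` (FTS/BFS), ``diet``, ``timepoint``, ``tank``, ``fish``.
    """

    def __init__(self, counts: pd.DataFrame, metadata: Optional[pd.DataFrame] = None):
        counts = counts.copy()
        if counts.index.has_duplicates:
            raise ValueError("duplicate sample ids")
        if counts.columns.has_duplicates:
            raise ValueError("duplicate ASV ids")
        arr = counts.to_numpy()
        if arr.size and (arr < 0).any():
            raise ValueError("counts must be non-negative")
        if arr.size and not np.allclose(arr, np.round(arr)):
            raise ValueError("counts must be integers")
        counts = counts.astype(np.int64)
        if metadata is not None:
            metadata = metadata.copy()
            if not counts.index.equals(metadata.index):
                if set(counts.index) != set(metadata.index):
                    raise ValueError("metadata rows do not align 1:1 with count rows")
                metadata = metadata.loc[counts.index]
        self.counts = counts
        self.metadata = metadata

    # -- basic properties -------------------------------------------------
    @property
    def sample_ids(self) -> list:
        return list(self.counts.index)

    @property
    def asv_ids(self) -> list:
        return list(self.counts.columns)

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_asvs(self) -> int:
        return self.counts.shape[1]

    def depths(self) -> pd.Series:
        """Per-sample total read counts."""
        return self.counts.sum(axis=1)

    def relative_abundance(self) -> pd.DataFrame:
        """Row-normalised proportions; rejects empty samples."""
        depths = self.depths()
        if (depths == 0).any():
            empty = list(depths.index[depths == 0])
            raise ValueError(f"samples with zero reads: {empty}")
        return self.counts.div(depths, axis=0)

    # -- subsetting -------------------------------------------------------
    def select_samples(self, sample_ids: Sequence) -> "AsvTable":
        counts = self.counts.loc[list(sample_ids)]
        meta = self.metadata.loc[list(sample_ids)] if self.metadata is not None else None
        return AsvTable(counts, meta)

    def select_asvs(self, asv_ids: Sequence) -> "AsvTable":
        return AsvTable(self.counts[list(asv_ids)], self.metadata)

    def drop_empty_asvs(self) -> "AsvTable":
        keep = self.counts.columns[self.counts.sum(axis=0) > 0]
        return AsvTable(self.counts[keep], self.metadata)

    def where(self, **conditions) -> "AsvTable":
        """Subset samples by metadata equality, e.g. ``table.where(system="BFS")``."""
        if self.metadata is None:
            raise ValueError("table has no metadata")
        mask = pd.Series(True, index=self.counts.index)
        for col, val in conditions.items():
            if col not in self.metadata.columns:
                raise KeyError(f"metadata column {col!r} not present")
            mask &= self.metadata[col] == val
        return self.select_samples(list(self.counts.index[mask]))

    def grouping(self, column: str) -> pd.Series:
        """Metadata column as a per-sample grouping vector."""
        if self.metadata is None or column not in self.metadata.columns:
            raise KeyError(f"metadata column {column!r} not present")
        return self.metadata[column]

    def groups(self, column: str) -> Mapping[object, "AsvTable"]:
        """Split the table by a metadata column."""
        g = self.grouping(column)
        return {
            level: self.select_samples(list(g.index[g == level]))
            for level in pd.unique(g)
        }

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"AsvTable({self.n_samples} samples x {self.n_asvs} ASVs)"
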