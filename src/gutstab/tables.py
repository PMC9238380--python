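"""Core in-memory containers for the analysis.

All tabular data ride on :class:`pandas.DataFrame`; the thin wrappers here
add the domain invariants (non-negativity, unique ids, proportion columns
summing to one) and the metadata (kingdom, taxonomic level) that the
downstream statistics need.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FeatureTable",
    "SampleMetadata",
    "DissimilarityMatrix",
    "TableError",
]

#: tolerance for "each proportion column sums to 1"
_PROP_TOL = 1e-9


class TableError(ValueError):
    """Raised when a table violates a structural invariant."""


@dataclass(frozen=True)
class FeatureTable:
    """A feature-by-sample abundance matrix for one microbial kingdom.

    Parameters
    ----------
    data :
        DataFrame with feature ids as the index and sample ids as columns.
        Entries are non-negative counts or proportions.
    kingdom :
        Compartment label, e.g. ``"bacterial"``, ``"FVP"`` (free viral
        particles), ``"IV"`` (inducible viruses) or ``"VOG-abundance"``.
    level :
        Taxonomic level of the rows (``"genus"`` for all taxonomic work).
    mode :
        ``"counts"`` or ``"proportions"``.
    taxonomy :
        Optional map from feature id to its lineage, an ordered sequence of
        labels parallel to ``taxonomy_levels``.
    taxonomy_levels :
        Names of the ranks in each lineage, most inclusive first.
    """

    data: pd.DataFrame
    kingdom: str = "bacterial"
    level: str = "genus"
    mode: str = "counts"
    taxonomy: Mapping[str, Sequence[str]] | None = None
    taxonomy_levels: tuple[str, ...] = field(default=("genus",))

    def __post_init__(self) -> None:
        df = self.data
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise TableError(f"duplicate feature ids: {dups}")
        if df.columns.has_duplicates:
            dups = df.columns[df.columns.duplicated()].unique().tolist()
            raise TableError(f"duplicate sample ids: {dups}")
        values = df.to_numpy(dtype=float)
        if values.size and np.nanmin(values) < 0:
            rows = df.index[(values < 0).any(axis=1)].tolist()
            raise TableError(f"negative abundances in features: {rows}")
        if self.mode not in ("counts", "proportions"):
            raise TableError(f"unknown mode {self.mode!r}")
        if self.mode == "proportions" and values.size:
            sums = values.sum(axis=0)
            bad = ~np.isclose(sums, 1.0, rtol=0, atol=_PROP_TOL)
            empty = sums == 0
            if np.any(bad & ~empty):
                cols = df.columns[bad & ~empty].tolist()
                raise TableError(f"proportion columns not summing to 1: {cols}")
            if np.any(empty):
                cols = df.columns[empty].tolist()
                raise TableError(f"empty (all-zero) proportion columns: {cols}")

    # -- convenience accessors -------------------------------------------------
    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def with_data(self, data: pd.DataFrame, **changes) -> "FeatureTable":
        return replace(self, data=data, **changes)

    def subset_samples(self, sample_ids: Sequence[str]) -> "FeatureTable":
        missing = [s for s in sample_ids if s not in self.data.columns]
        if missing:
            raise TableError(f"samples not in table: {missing}")
        return self.with_data(self.data.loc[:, list(sample_ids)])


@dataclass(frozen=True)
class SampleMetadata:
    """Maps each sample id to subject, diet arm and time point.

    ``frame`` is indexed by sample id with columns ``subject``, ``arm``
    and ``time_point``.
    """

    frame: pd.DataFrame
    time_order: tuple[str, ...] = ("pre", "mid", "post")

    def __post_init__(self) -> None:
        required = {"subject", "arm", "time_point"}
        missing = required - set(self.frame.columns)
        if missing:
            raise TableError(f"metadata missing columns: {sorted(missing)}")
        if self.frame.index.has_duplicates:
            raise TableError("duplicate sample ids in metadata")
        unknown = set(self.frame["time_point"]) - set(self.time_order)
        if unknown:
            raise TableError(f"time points outside declared order: {sorted(unknown)}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame.index)

    @property
    def subjects(self) -> list[str]:
        return sorted(self.frame["subject"].unique())

    @property
    def arms(self) -> list[str]:
        return sorted(self.frame["arm"].unique())

    def samples_of(self, subject: str) -> list[str]:
        return list(self.frame.index[self.frame["subject"] == subject])

    def arm_of(self, subject: str) -> str:
        arms = self.frame.loc[self.frame["subject"] == subject, "arm"].unique()
        if len(arms) != 1:
            raise TableError(f"subject {subject!r} maps to arms {list(arms)}")
        return arms[0]

    def subset(self, sample_ids: Sequence[str]) -> "SampleMetadata":
        return SampleMetadata(self.frame.loc[list(sample_ids)], self.time_order)

    def time_index(self, time_point: str) -> int:
        return self.time_order.index(time_point)


@dataclass(frozen=True)
class DissimilarityMatrix:
    """Square symmetric pairwise distance structure over samples."""

    data: pd.DataFrame
    metric: str = "unknown"

    def __post_init__(self) -> None:
        df = self.data
        if list(df.index) != list(df.columns):
            raise TableError("dissimilarity matrix index and columns differ")
        m = df.to_numpy(dtype=float)
        if m.shape[0] != m.shape[1]:
            raise TableError("dissimilarity matrix is not square")
        if not np.allclose(m, m.T, atol=1e-12):
            raise TableError("dissimilarity matrix is not symmetric")
        if np.any(np.abs(np.diag(m)) > 1e-12):
            raise TableError("dissimilarity matrix has a nonzero diagonal")
        if m.size and m.min() < 0:
            raise TableError("negative dissimilarities")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def submatrix(self, sample_ids: Sequence[str]) -> "DissimilarityMatrix":
        ids = list(sample_ids)
        return DissimilarityMatrix(self.data.loc[ids, ids], self.metric)
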