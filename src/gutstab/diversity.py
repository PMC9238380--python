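"""Alpha- and beta-diversity metrics, written out from their definitions.

Alpha diversity is summarised by taxonomic richness, Fisher's log-series
alpha and Simpson dominance; beta diversity by Bray-Curtis dissimilarity
(taxonomic tables) and by the Canberra distance normalised by the number of
non-zero feature pairs (the vegan convention), used for functional gene
composition.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .tables import DissimilarityMatrix, FeatureTable, TableError

__all__ = [
    "aggregate_to_level",
    "to_proportions",
    "richness",
    "fisher_alpha",
    "simpson_dominance",
    "bray_curtis_matrix",
    "canberra_matrix",
    "alpha_diversity_table",
]


def aggregate_to_level(table: FeatureTable, level: str) -> FeatureTable:
    """Sum features that share the same lineage prefix at ``level``.

    Per-sample totals are conserved exactly. The table must carry a
    taxonomy covering every feature; features whose lineages agree on all
    ranks down to ``level`` are merged into one row named by that prefix's
    final label.
    """
    if level == table.level:
        return table
    if level not in table.taxonomy_levels:
        raise TableError(
            f"level {level!r} not among taxonomy levels {table.taxonomy_levels}"
        )
    if table.taxonomy is None:
        raise TableError("table has no taxonomy; cannot aggregate")
    missing = [f for f in table.feature_ids if f not in table.taxonomy]
    if missing:
        raise TableError(f"features missing a lineage: {missing}")

    depth = table.taxonomy_levels.index(level) + 1
    prefixes = {f: tuple(table.taxonomy[f][:depth]) for f in table.feature_ids}
    short = [f for f, p in prefixes.items() if len(p) < depth]
    if short:
        raise TableError(f"lineages shorter than level {level!r}: {short}")

    groups = pd.Series({f: ";".join(p) for f, p in prefixes.items()})
    aggregated = table.data.groupby(groups, sort=True).sum()
    aggregated.index.name = table.data.index.name
    new_tax = {
        ";".join(p): list(p) for p in {tuple(v) for v in prefixes.values()}
    }
    return FeatureTable(
        aggregated,
        kingdom=table.kingdom,
        level=level,
        mode=table.mode,
        taxonomy=new_tax,
        taxonomy_levels=table.taxonomy_levels[:depth],
    )


def to_proportions(table: FeatureTable) -> FeatureTable:
    """Convert a count table to per-sample relative abundances."""
    if table.mode == "proportions":
        return table
    values = table.values()
    sums = values.sum(axis=0)
    zero = sums == 0
    if np.any(zero):
        cols = [c for c, z in zip(table.sample_ids, zero) if z]
        raise TableError(f"cannot normalise all-zero sample columns: {cols}")
    props = pd.DataFrame(
        values / sums, index=table.data.index, columns=table.data.columns
    )
    return table.with_data(props, mode="proportions")


def richness(sample: Sequence[float] | np.ndarray) -> int:
    """Number of features with strictly positive abundance."""
    arr = np.asarray(sample, dtype=float)
    if arr.size and arr.min() < 0:
        raise TableError("negative abundances in sample")
    return int(np.count_nonzero(arr > 0))


def fisher_alpha(S: int, N: int, *, rtol: float = 1e-10) -> float:
    """Fisher's log-series alpha: the positive root of S = a*ln(1 + N/a).

    Parameters
    ----------
    S : number of observed species (1 <= S < N)
    N : number of observed individuals

    The objective a*ln(1+N/a) - S is increasing in a, approaches 0 as
    a -> 0+ and N as a -> inf, so a unique root exists whenever S < N;
    it is bracketed and solved with Brent's method to relative tolerance
    ``rtol``.
    """
    if S < 1:
        raise ValueError(f"species count must be >= 1, got {S}")
    if S >= N:
        raise ValueError(
            f"Fisher's alpha is unbounded when S >= N (S={S}, N={N}): "
            "the log-series requires more individuals than species"
        )

    def objective(a: float) -> float:
        return a * np.log1p(N / a) - S

    lo, hi = 1e-12, 1.0
    while objective(hi) < 0:
        hi *= 2.0
        if hi > 1e18:  # pragma: no cover - unreachable for valid S < N
            raise RuntimeError("failed to bracket Fisher's alpha")
    return float(brentq(objective, lo, hi, rtol=rtol, maxiter=200))


def simpson_dominance(props: Sequence[float] | np.ndarray, *, tol: float = 1e-8) -> float:
    """Simpson dominance sum(p_i^2) of a proportion vector (higher = more dominated)."""
    p = np.asarray(props, dtype=float)
    if p.size == 0:
        raise TableError("empty proportion vector")
    if p.min() < 0:
        raise TableError("negative proportions")
    total = p.sum()
    if not np.isclose(total, 1.0, rtol=0, atol=tol):
        raise TableError(f"proportions sum to {total}, not 1")
    return float(np.sum(p**2))


def _pairwise(values: np.ndarray, func) -> np.ndarray:
    n = values.shape[1]
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = func(values[:, i], values[:, j])
    return out


def _bray_curtis(x: np.ndarray, y: np.ndarray) -> float:
    denom = np.sum(x + y)
    if denom == 0:
        raise TableError("Bray-Curtis undefined for a pair of all-zero samples")
    return float(np.sum(np.abs(x - y)) / denom)


def _canberra(x: np.ndarray, y: np.ndarray) -> float:
    s = x + y
    nz = s > 0
    n_nz = int(np.count_nonzero(nz))
    if n_nz == 0:
        raise TableError("Canberra undefined for a pair of all-zero samples")
    return float(np.sum(np.abs(x[nz] - y[nz]) / s[nz]) / n_nz)


def bray_curtis_matrix(table: FeatureTable, *, on: str = "counts") -> DissimilarityMatrix:
    """Pairwise Bray-Curtis dissimilarity, d = sum|x-y| / sum(x+y).

    ``on="counts"`` (default) uses the table's values as given;
    ``on="proportions"`` normalises each sample column first, which makes
    every pair denominator equal 2 and the metric depend only on relative
    composition.
    """
    if on not in ("counts", "proportions"):
        raise ValueError(f"unknown basis {on!r}")
    if len(table.sample_ids) < 2:
        raise TableError("need at least two samples for a dissimilarity matrix")
    t = to_proportions(table) if on == "proportions" else table
    matrix = _pairwise(t.values(), _bray_curtis)
    return DissimilarityMatrix(
        pd.DataFrame(matrix, index=t.sample_ids, columns=t.sample_ids),
        metric="bray-curtis",
    )


def canberra_matrix(table: FeatureTable) -> DissimilarityMatrix:
    """Pairwise Canberra distance averaged over non-zero feature pairs.

    d(x, y) = (1/NZ) * sum over features with x_i + y_i > 0 of
    |x_i - y_i| / (x_i + y_i); features absent from both samples are
    ignored. Dividing by NZ keeps d in [0, 1] and matches the
    normalisation used by vegan's ``vegdist(..., "canberra")``.
    """
    if len(table.sample_ids) < 2:
        raise TableError("need at least two samples for a dissimilarity matrix")
    matrix = _pairwise(table.values(), _canberra)
    return DissimilarityMatrix(
        pd.DataFrame(matrix, index=table.sample_ids, columns=table.sample_ids),
        metric="canberra",
    )


def alpha_diversity_table(table: FeatureTable) -> pd.DataFrame:
    """Per-sample richness, Fisher-alpha and Simpson dominance.

    Fisher-alpha is reported as NaN for samples where it is undefined
    (fewer than 1 taxon, or as many taxa as individuals — possible only
    for very shallow samples).
    """
    counts = table.values()
    records = []
    for j, sample in enumerate(table.sample_ids):
        col = counts[:, j]
        S = richness(col)
        N = col.sum()
        try:
            alpha = fisher_alpha(S, int(round(N))) if S >= 1 else float("nan")
        except ValueError:
            alpha = float("nan")
        total = col.sum()
        dom = simpson_dominance(col / total) if total > 0 else float("nan")
        records.append(
            {"sample": sample, "richness": S, "fisher_alpha": alpha, "simpson_dominance": dom}
        )
    return pd.DataFrame.from_records(records).set_index("sample")
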