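"""Principal coordinates analysis and permutation inference.

Implements classical metric scaling (PCoA) of a dissimilarity matrix,
one-way PERMANOVA with optional repeated-measures-restricted (stratified)
permutations, its pairwise variant with Bonferroni adjustment, ANOSIM, and
the Kruskal-Wallis rank-sum test. Permutation p-values use the add-one
estimator p = (1 + #{T_perm >= T_obs}) / (1 + n_perm), so p is never 0 and
never below 1/(n_perm + 1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2, rankdata

from .tables import DissimilarityMatrix, TableError

__all__ = [
    "PCoAResult",
    "PermanovaResult",
    "AnosimResult",
    "pcoa",
    "permanova",
    "pairwise_permanova",
    "anosim",
    "kruskal_wallis",
    "bonferroni",
]

_EIG_TOL = 1e-9  # relative cutoff separating "positive" from numerically-zero eigenvalues


@dataclass(frozen=True)
class PCoAResult:
    """Scores, eigenvalues and explained-variance proportions from PCoA.

    ``scores`` has one row per sample and one column per retained
    (positive-eigenvalue) axis, named PC1, PC2, ...; ``eigenvalues``
    contains the full spectrum in descending order, negative eigenvalues
    included for diagnostics even though their axes carry no scores.
    """

    scores: pd.DataFrame
    eigenvalues: np.ndarray
    proportion_explained: np.ndarray

    @property
    def sample_ids(self) -> list[str]:
        return list(self.scores.index)

    def pc1(self) -> pd.Series:
        if self.scores.shape[1] == 0:
            # degenerate ordination (all samples coincide): PC1 is all zeros
            return pd.Series(0.0, index=self.scores.index, name="PC1")
        return self.scores["PC1"]


@dataclass(frozen=True)
class PermanovaResult:
    pseudo_f: float
    r_squared: float
    p_value: float
    n_permutations: int
    strata: str | None = None
    permuted_f_mean: float = float("nan")
    permuted_f_q95: float = float("nan")
    groups_compared: tuple[str, ...] = field(default_factory=tuple)
    p_adjusted: float | None = None

    def as_dict(self) -> dict:
        d = {
            "pseudo_f": self.pseudo_f,
            "r_squared": self.r_squared,
            "p_value": self.p_value,
            "n_permutations": self.n_permutations,
            "strata": self.strata,
            "permuted_f_mean": self.permuted_f_mean,
            "permuted_f_q95": self.permuted_f_q95,
        }
        if self.groups_compared:
            d["groups_compared"] = list(self.groups_compared)
        if self.p_adjusted is not None:
            d["p_adjusted"] = self.p_adjusted
        return d


@dataclass(frozen=True)
class AnosimResult:
    r: float
    p_value: float
    n_permutations: int

    def as_dict(self) -> dict:
        return {"r": self.r, "p_value": self.p_value, "n_permutations": self.n_permutations}


# ---------------------------------------------------------------------------
# PCoA
# ---------------------------------------------------------------------------

def _gower_center(d_squared: np.ndarray) -> np.ndarray:
    n = d_squared.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    return -0.5 * j @ d_squared @ j


def _cailliez_constant(d: np.ndarray) -> float:
    """Smallest additive constant making the off-diagonal distances Euclidean."""
    n = d.shape[0]
    delta1 = _gower_center(d**2)
    delta2 = _gower_center(d)
    upper = np.hstack([np.zeros((n, n)), 2.0 * delta1])
    lower = np.hstack([-np.eye(n), -4.0 * delta2])
    eigvals = np.linalg.eigvals(np.vstack([upper, lower]))
    c = float(np.max(eigvals.real))
    return max(c, 0.0)


def pcoa(D: DissimilarityMatrix, *, correction: str = "none") -> PCoAResult:
    """Classical metric scaling of a dissimilarity matrix.

    The Gower-centred matrix -1/2 J D^2 J is eigendecomposed; axis k's
    scores are eigenvector_k * sqrt(eigenvalue_k) for positive eigenvalues.
    Negative eigenvalues (non-Euclidean input) are reported but contribute
    no axes; pass ``correction="cailliez"`` to add the smallest constant
    that makes the off-diagonal distances Euclidean first. Each axis's sign
    is fixed by making its largest-magnitude score positive.
    """
    ids = D.sample_ids
    n = len(ids)
    if n < 3:
        raise TableError(f"PCoA needs at least 3 samples, got {n}")
    d = D.values()
    if correction == "cailliez":
        c = _cailliez_constant(d)
        if c > 0:
            d = d + c * (1 - np.eye(n))
    elif correction != "none":
        raise ValueError(f"unknown correction {correction!r}")

    b = _gower_center(d**2)
    eigvals, eigvecs = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]

    scale = max(abs(eigvals[0]), 1.0) if eigvals.size else 1.0
    positive = eigvals > _EIG_TOL * scale
    pos_vals = eigvals[positive]
    scores = eigvecs[:, positive] * np.sqrt(pos_vals)

    # reproducible axis orientation: largest-|score| entry positive
    for k in range(scores.shape[1]):
        col = scores[:, k]
        if col[np.argmax(np.abs(col))] < 0:
            scores[:, k] = -col

    total_pos = pos_vals.sum()
    prop = pos_vals / total_pos if total_pos > 0 else pos_vals
    frame = pd.DataFrame(
        scores, index=ids, columns=[f"PC{k + 1}" for k in range(scores.shape[1])]
    )
    return PCoAResult(scores=frame, eigenvalues=eigvals, proportion_explained=prop)


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------

def _group_indices(labels: np.ndarray) -> list[np.ndarray]:
    return [np.flatnonzero(labels == g) for g in np.unique(labels)]


def _permanova_f(d_squared: np.ndarray, labels: np.ndarray, sst: float) -> tuple[float, float]:
    n = d_squared.shape[0]
    ssw = 0.0
    n_groups = 0
    for idx in _group_indices(labels):
        n_groups += 1
        if idx.size > 1:
            sub = d_squared[np.ix_(idx, idx)]
            ssw += sub.sum() / (2.0 * idx.size)
    ssa = sst - ssw
    df_a = n_groups - 1
    df_w = n - n_groups
    if df_w <= 0 or ssw <= 0:
        return float("inf"), (ssa / sst if sst > 0 else 0.0)
    f = (ssa / df_a) / (ssw / df_w)
    r2 = ssa / sst if sst > 0 else 0.0
    return float(f), float(r2)


def _stratified_permutation(
    labels: np.ndarray, strata: np.ndarray | None, rng: np.random.Generator
) -> np.ndarray:
    """Permute labels, restricted within strata when given.

    Labels never cross a stratum boundary: each stratum's labels are
    shuffled among that stratum's own positions only.
    """
    if strata is None:
        return rng.permutation(labels)
    permuted = labels.copy()
    for s in np.unique(strata):
        idx = np.flatnonzero(strata == s)
        permuted[idx] = labels[idx[rng.permutation(idx.size)]]
    return permuted


def _check_strata(labels: np.ndarray, strata: np.ndarray) -> None:
    for s in np.unique(strata):
        idx = np.flatnonzero(strata == s)
        if len(np.unique(labels[idx])) < 2:
            warnings.warn(
                f"stratum {s!r} holds a single group label; its permutations are "
                "no-ops and it contributes no label exchange",
                stacklevel=3,
            )


def permanova(
    D: DissimilarityMatrix,
    groups: Mapping[str, str] | Sequence[str],
    *,
    strata: Mapping[str, str] | Sequence[str] | None = None,
    n_perm: int = 999,
    seed: int = 0,
) -> PermanovaResult:
    """One-way PERMANOVA on a dissimilarity matrix with optional strata.

    The total sum of squares is sum(d_ij^2)/n over all pairs; the within
    sum of squares accumulates each group's pairwise d^2 divided by group
    size. The pseudo-F compares among- to within-group mean squares and
    the p-value comes from ``n_perm`` seeded permutations of the group
    labels — shuffled only within each stratum when ``strata`` is given
    (e.g. subject as stratum for repeated measures, so time-point labels
    permute within, never across, subjects).
    """
    ids = D.sample_ids
    labels = _align_labels(groups, ids, "groups")
    if len(np.unique(labels)) < 2:
        raise TableError("PERMANOVA requires at least two groups")
    strata_arr = None
    strata_desc = None
    if strata is not None:
        strata_arr = _align_labels(strata, ids, "strata")
        strata_desc = f"{len(np.unique(strata_arr))} strata"
        _check_strata(labels, strata_arr)

    d_squared = D.values() ** 2
    n = len(ids)
    sst = d_squared.sum() / (2.0 * n)
    f_obs, r2 = _permanova_f(d_squared, labels, sst)

    rng = np.random.default_rng(seed)
    f_perm = np.empty(n_perm)
    for i in range(n_perm):
        perm = _stratified_permutation(labels, strata_arr, rng)
        f_perm[i], _ = _permanova_f(d_squared, perm, sst)
    p = (1.0 + np.count_nonzero(f_perm >= f_obs)) / (1.0 + n_perm)

    finite = f_perm[np.isfinite(f_perm)]
    return PermanovaResult(
        pseudo_f=f_obs,
        r_squared=r2,
        p_value=float(p),
        n_permutations=n_perm,
        strata=strata_desc,
        permuted_f_mean=float(finite.mean()) if finite.size else float("nan"),
        permuted_f_q95=float(np.quantile(finite, 0.95)) if finite.size else float("nan"),
    )


def _align_labels(
    labels: Mapping[str, str] | Sequence[str], ids: list[str], what: str
) -> np.ndarray:
    if isinstance(labels, Mapping):
        missing = [s for s in ids if s not in labels]
        if missing:
            raise TableError(f"{what} missing for samples: {missing}")
        return np.asarray([labels[s] for s in ids], dtype=object)
    arr = np.asarray(list(labels), dtype=object)
    if arr.size != len(ids):
        raise TableError(f"{what} length {arr.size} != number of samples {len(ids)}")
    return arr


def pairwise_permanova(
    D: DissimilarityMatrix,
    groups: Mapping[str, str] | Sequence[str],
    *,
    strata: Mapping[str, str] | Sequence[str] | None = None,
    n_perm: int = 999,
    seed: int = 0,
) -> list[PermanovaResult]:
    """PERMANOVA on every unordered pair of groups, Bonferroni-adjusted.

    Each pair is tested on the sub-matrix of its samples; strata restrict
    permutations inside the subset the same way as in :func:`permanova`.
    """
    ids = D.sample_ids
    labels = _align_labels(groups, ids, "groups")
    strata_arr = _align_labels(strata, ids, "strata") if strata is not None else None
    unique = sorted(np.unique(labels))
    if len(unique) < 2:
        raise TableError("pairwise PERMANOVA requires at least two groups")

    pairs = list(combinations(unique, 2))
    results = []
    for k, (a, b) in enumerate(pairs):
        mask = (labels == a) | (labels == b)
        sub_ids = [s for s, m in zip(ids, mask) if m]
        sub_groups = {s: g for s, g, m in zip(ids, labels, mask) if m}
        sub_strata = (
            {s: st for s, st, m in zip(ids, strata_arr, mask) if m}
            if strata_arr is not None
            else None
        )
        res = permanova(
            D.submatrix(sub_ids),
            sub_groups,
            strata=sub_strata,
            n_perm=n_perm,
            seed=seed + k,
        )
        results.append(res)
    adjusted = bonferroni([r.p_value for r in results])
    return [
        PermanovaResult(
            pseudo_f=r.pseudo_f,
            r_squared=r.r_squared,
            p_value=r.p_value,
            n_permutations=r.n_permutations,
            strata=r.strata,
            permuted_f_mean=r.permuted_f_mean,
            permuted_f_q95=r.permuted_f_q95,
            groups_compared=pair,
            p_adjusted=adj,
        )
        for r, pair, adj in zip(results, pairs, adjusted)
    ]


# ---------------------------------------------------------------------------
# ANOSIM
# ---------------------------------------------------------------------------

def anosim(
    D: DissimilarityMatrix,
    groups: Mapping[str, str] | Sequence[str],
    *,
    n_perm: int = 999,
    seed: int = 0,
) -> AnosimResult:
    """ANOSIM: rank-based separation statistic on a dissimilarity matrix.

    R = (mean between-group rank - mean within-group rank) / (M/2) with
    M = n(n-1)/2 pairwise distances ranked jointly (average ranks on
    ties); R = 1 means every between-group distance exceeds every
    within-group one. Depends on the distances only through their ranks,
    so any monotone transform of D leaves R unchanged.
    """
    ids = D.sample_ids
    labels = _align_labels(groups, ids, "groups")
    if len(np.unique(labels)) < 2:
        raise TableError("ANOSIM requires at least two groups")
    d = D.values()
    n = len(ids)
    iu = np.triu_indices(n, k=1)
    dist = d[iu]
    if np.all(dist == dist[0]):
        warnings.warn("all pairwise distances tied; ANOSIM R set to 0", stacklevel=2)
        return AnosimResult(r=0.0, p_value=1.0, n_permutations=n_perm)
    ranks = rankdata(dist)
    m = ranks.size
    denom = m / 2.0

    def r_stat(lab: np.ndarray) -> float:
        within = lab[iu[0]] == lab[iu[1]]
        return float((ranks[~within].mean() - ranks[within].mean()) / denom)

    r_obs = r_stat(labels)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        if r_stat(rng.permutation(labels)) >= r_obs:
            count += 1
    p = (1.0 + count) / (1.0 + n_perm)
    return AnosimResult(r=r_obs, p_value=float(p), n_permutations=n_perm)


# ---------------------------------------------------------------------------
# Rank tests
# ---------------------------------------------------------------------------

def kruskal_wallis(
    values: Sequence[float], groups: Sequence[str]
) -> tuple[float, float]:
    """Kruskal-Wallis rank-sum H with tie correction and chi-square p.

    H = 12/(n(n+1)) * sum n_g (rbar_g - (n+1)/2)^2, divided by the tie
    correction 1 - sum(t^3 - t)/(n^3 - n); p from chi-square with
    (groups - 1) degrees of freedom.
    """
    vals = np.asarray(values, dtype=float)
    labs = np.asarray(list(groups), dtype=object)
    if vals.size != labs.size:
        raise TableError("values and groups differ in length")
    if vals.size < 2:
        raise TableError("Kruskal-Wallis needs at least two observations")
    uniq = np.unique(labs)
    if uniq.size < 2:
        raise TableError("Kruskal-Wallis requires at least two groups")
    for g in uniq:
        if np.count_nonzero(labs == g) == 0:  # pragma: no cover - np.unique excludes
            raise TableError(f"empty group {g!r}")

    n = vals.size
    ranks = rankdata(vals)
    h = 0.0
    for g in uniq:
        idx = labs == g
        n_g = int(np.count_nonzero(idx))
        h += n_g * (ranks[idx].mean() - (n + 1) / 2.0) ** 2
    h *= 12.0 / (n * (n + 1))

    _, tie_counts = np.unique(vals, return_counts=True)
    correction = 1.0 - np.sum(tie_counts**3 - tie_counts) / (n**3 - n)
    if correction == 0:
        return 0.0, 1.0  # all observations identical
    h /= correction
    p = float(chi2.sf(h, df=uniq.size - 1))
    return float(h), p


def bonferroni(p_values: Sequence[float]) -> list[float]:
    """Bonferroni adjustment: p*m capped at 1."""
    ps = list(p_values)
    for p in ps:
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"p-value out of [0, 1]: {p}")
    m = len(ps)
    return [min(1.0, p * m) for p in ps]
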