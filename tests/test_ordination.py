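"""PCoA and permutation inference against enumeration and coordinate oracles."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from gutstab import anosim, bonferroni, kruskal_wallis, pairwise_permanova, pcoa, permanova
from gutstab.ordination import _stratified_permutation
from gutstab.tables import DissimilarityMatrix, TableError

from .conftest import euclidean_dissimilarity


# ---------------------------------------------------------------------------
# PCoA
# ---------------------------------------------------------------------------

def test_pcoa_all_zero_distances_give_zero_scores():
    ids = list("abcd")
    D = DissimilarityMatrix(pd.DataFrame(np.zeros((4, 4)), index=ids, columns=ids))
    res = pcoa(D)
    assert res.scores.shape[1] == 0
    assert np.allclose(res.eigenvalues, 0, atol=1e-9)
    assert (res.pc1() == 0).all()


def test_pcoa_recovers_one_dimensional_layout():
    D = euclidean_dissimilarity([0.0, 1.0, 3.0])
    res = pcoa(D)
    positive = res.eigenvalues[res.eigenvalues > 1e-9]
    assert positive.size == 1
    s = res.scores["PC1"].to_numpy()
    diffs = np.abs(s[:, None] - s[None, :])
    assert np.allclose(diffs, D.values(), atol=1e-9)
    # axis scores are centred
    assert abs(s.sum()) < 1e-9


def test_pcoa_total_variance_matches_coordinate_oracle():
    rng = np.random.default_rng(3)
    pts = rng.normal(size=(9, 2))
    res = pcoa(euclidean_dissimilarity(pts))
    centered = pts - pts.mean(axis=0)
    assert res.eigenvalues[res.eigenvalues > 0].sum() == pytest.approx(
        (centered**2).sum(), abs=1e-8
    )


def test_pcoa_reconstructs_euclidean_distances_from_axes():
    rng = np.random.default_rng(4)
    pts = rng.normal(size=(8, 3))
    D = euclidean_dissimilarity(pts)
    res = pcoa(D)
    s = res.scores.to_numpy()
    rec = np.sqrt(((s[:, None, :] - s[None, :, :]) ** 2).sum(-1))
    assert np.allclose(rec, D.values(), atol=1e-6)


def test_pcoa_matches_direct_eigendecomposition_oracle():
    rng = np.random.default_rng(5)
    pts = rng.normal(size=(7, 2))
    D = euclidean_dissimilarity(pts)
    res = pcoa(D)
    # independent oracle: eigendecompose the double-centred matrix directly
    d2 = D.values() ** 2
    n = d2.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    w, v = np.linalg.eigh(-0.5 * j @ d2 @ j)
    w_desc = np.sort(w)[::-1]
    k = res.scores.shape[1]
    assert np.allclose(res.eigenvalues[:k], w_desc[:k], atol=1e-10)
    oracle_scores = np.abs(v[:, np.argsort(w)[::-1][:k]] * np.sqrt(w_desc[:k]))
    assert np.allclose(np.abs(res.scores.to_numpy()), oracle_scores, atol=1e-6)


def test_pcoa_negative_eigenvalues_reported_not_scored():
    # Bray-Curtis of this count table is non-Euclidean (verified by direct
    # eigendecomposition of the Gower-centred matrix)
    from gutstab import bray_curtis_matrix

    from .conftest import table_from_array

    counts = np.array(
        [
            [8, 10, 9, 6, 10],
            [9, 9, 0, 4, 6],
            [2, 3, 6, 8, 5],
            [1, 6, 8, 2, 5],
            [3, 9, 0, 4, 8],
        ]
    )
    D = bray_curtis_matrix(table_from_array(counts))
    res = pcoa(D)
    assert res.eigenvalues.min() < -1e-6
    assert res.scores.shape[1] < len(D.sample_ids)
    corrected = pcoa(D, correction="cailliez")
    scale = abs(corrected.eigenvalues[0])
    assert corrected.eigenvalues.min() >= -1e-6 * scale


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------

def _two_cluster_matrix():
    d = np.full((6, 6), 0.99)
    for block in (slice(0, 3), slice(3, 6)):
        d[block, block] = 0.01
    np.fill_diagonal(d, 0.0)
    ids = [f"s{i}" for i in range(6)]
    return DissimilarityMatrix(pd.DataFrame(d, index=ids, columns=ids))


def test_permanova_separated_clusters():
    D = _two_cluster_matrix()
    res = permanova(D, ["a"] * 3 + ["b"] * 3, n_perm=999, seed=0)
    assert res.r_squared > 0.9
    # minimum achievable p for 999 permutations of a 3+3 split: ties at the
    # 2/20 label assignments reproducing the split exactly
    assert res.p_value <= 2 * (1 / 20) + 0.03


def test_permanova_monte_carlo_agrees_with_exhaustive_enumeration():
    rng = np.random.default_rng(6)
    D = euclidean_dissimilarity(rng.normal(size=(6, 2)))
    labels = ["a", "a", "a", "b", "b", "b"]

    def pseudo_f(lab):
        return permanova(D, list(lab), n_perm=1, seed=0).pseudo_f

    f_obs = pseudo_f(labels)
    f_all = []
    for comb in combinations(range(6), 3):
        lab = np.where(np.isin(np.arange(6), comb), "a", "b")
        f_all.append(pseudo_f(lab))
    p_exact = np.mean([f >= f_obs - 1e-12 for f in f_all])

    n_perm = 10_000
    p_mc = permanova(D, labels, n_perm=n_perm, seed=7).p_value
    se = np.sqrt(p_exact * (1 - p_exact) / n_perm)
    assert abs(p_mc - p_exact) <= 3 * se + 2 / n_perm


def test_permanova_invariant_to_sample_order():
    rng = np.random.default_rng(8)
    D = euclidean_dissimilarity(rng.normal(size=(8, 2)))
    groups = dict(zip(D.sample_ids, ["a"] * 4 + ["b"] * 4))
    res = permanova(D, groups, n_perm=99, seed=1)
    shuffled_ids = list(np.random.default_rng(9).permutation(D.sample_ids))
    res2 = permanova(D.submatrix(shuffled_ids), groups, n_perm=99, seed=1)
    assert res2.pseudo_f == pytest.approx(res.pseudo_f, abs=1e-12)
    assert res2.r_squared == pytest.approx(res.r_squared, abs=1e-12)


def test_permanova_single_group_rejected():
    D = _two_cluster_matrix()
    with pytest.raises(TableError):
        permanova(D, ["a"] * 6, n_perm=9, seed=0)


def test_stratified_permutation_never_crosses_strata():
    rng = np.random.default_rng(10)
    labels = np.array(["pre", "mid", "post"] * 4, dtype=object)
    strata = np.repeat([f"subj{i}" for i in range(4)], 3)
    for _ in range(200):
        perm = _stratified_permutation(labels, strata, rng)
        for s in np.unique(strata):
            idx = strata == s
            assert sorted(perm[idx]) == sorted(labels[idx])


def test_permanova_warns_on_unpermutable_stratum():
    D = _two_cluster_matrix()
    groups = ["a", "a", "a", "b", "b", "b"]
    strata = ["u", "u", "u", "v", "v", "v"]  # each stratum single-group
    with pytest.warns(UserWarning, match="single group label"):
        res = permanova(D, groups, strata=strata, n_perm=49, seed=0)
    # nothing can permute, so every permuted F equals the observed F
    assert res.p_value == 1.0


def test_pairwise_permanova_pairs_and_consistency():
    rng = np.random.default_rng(11)
    D = euclidean_dissimilarity(rng.normal(size=(9, 2)))
    groups = dict(zip(D.sample_ids, ["a"] * 3 + ["b"] * 3 + ["c"] * 3))
    results = pairwise_permanova(D, groups, n_perm=99, seed=3)
    assert len(results) == 3  # 3 choose 2
    for res in results:
        pair_ids = [s for s in D.sample_ids if groups[s] in res.groups_compared]
        manual = permanova(
            D.submatrix(pair_ids), {s: groups[s] for s in pair_ids}, n_perm=1, seed=0
        )
        assert res.pseudo_f == pytest.approx(manual.pseudo_f, abs=1e-12)
        assert res.p_adjusted == pytest.approx(min(1.0, res.p_value * 3))


def test_pairwise_permanova_null_on_duplicated_groups():
    r2s, ps = [], []
    for seed in range(15):
        rng = np.random.default_rng(200 + seed)
        D = euclidean_dissimilarity(rng.normal(size=(10, 2)))
        groups = ["a"] * 5 + ["b"] * 5  # iid points, arbitrary labels
        res = pairwise_permanova(D, dict(zip(D.sample_ids, groups)), n_perm=99, seed=seed)[0]
        r2s.append(res.r_squared)
        ps.append(res.p_value)
    assert np.mean(r2s) < 0.25
    assert 0.2 < np.mean(ps)  # p roughly uniform, not piling at 0


# ---------------------------------------------------------------------------
# ANOSIM
# ---------------------------------------------------------------------------

def test_anosim_perfect_separation_gives_r_one():
    D = _two_cluster_matrix()
    res = anosim(D, ["a"] * 3 + ["b"] * 3, n_perm=99, seed=0)
    assert res.r == pytest.approx(1.0)
    assert res.p_value <= 0.15


def test_anosim_null_mean_r_near_zero():
    rs = []
    for seed in range(30):
        rng = np.random.default_rng(300 + seed)
        D = euclidean_dissimilarity(rng.normal(size=(8, 2)))
        labels = list(rng.permutation(["a"] * 4 + ["b"] * 4))
        rs.append(anosim(D, labels, n_perm=9, seed=seed).r)
    assert abs(np.mean(rs)) < 0.1


def test_anosim_invariant_to_monotone_distance_transform():
    rng = np.random.default_rng(12)
    D = euclidean_dissimilarity(rng.normal(size=(7, 2)))
    labels = ["a"] * 3 + ["b"] * 4
    res = anosim(D, labels, n_perm=99, seed=4)
    transformed = DissimilarityMatrix(
        pd.DataFrame(np.sqrt(D.values()), index=D.sample_ids, columns=D.sample_ids)
    )
    res_t = anosim(transformed, labels, n_perm=99, seed=4)
    assert res_t.r == pytest.approx(res.r, abs=1e-12)
    assert res_t.p_value == res.p_value


def test_anosim_label_renaming_leaves_r_unchanged():
    D = _two_cluster_matrix()
    r1 = anosim(D, ["a"] * 3 + ["b"] * 3, n_perm=9, seed=0).r
    r2 = anosim(D, ["zzz"] * 3 + ["qqq"] * 3, n_perm=9, seed=0).r
    assert r1 == r2


# ---------------------------------------------------------------------------
# rank tests
# ---------------------------------------------------------------------------

def test_kruskal_wallis_matches_scipy_and_is_shift_invariant():
    from scipy.stats import kruskal

    values = [1.0, 2.0, 3.0, 2.0, 10.0, 11.0, 12.0]
    groups = ["a", "a", "a", "a", "b", "b", "b"]
    h, p = kruskal_wallis(values, groups)
    h_ref, p_ref = kruskal(values[:4], values[4:])
    assert h == pytest.approx(h_ref, abs=1e-12)
    assert p == pytest.approx(p_ref, abs=1e-12)
    h_shift, _ = kruskal_wallis([v + 100 for v in values], groups)
    assert h_shift == pytest.approx(h, abs=1e-12)


def test_kruskal_wallis_identical_distributions_give_zero_h():
    h, p = kruskal_wallis([5.0, 5.0, 5.0, 5.0], ["a", "a", "b", "b"])
    assert h == 0.0
    assert p == 1.0


def test_kruskal_wallis_separated_groups_hand_formula():
    # ranks 1..6, group sums 6 and 15: H = 12/(6*7)*(3*(2-3.5)^2+3*(5-3.5)^2)
    h, _ = kruskal_wallis([1, 2, 3, 10, 11, 12], ["a"] * 3 + ["b"] * 3)
    expected = 12 / (6 * 7) * (3 * (2 - 3.5) ** 2 + 3 * (5 - 3.5) ** 2)
    assert h == pytest.approx(expected, abs=1e-12)


@pytest.mark.parametrize(
    "ps, expected",
    [
        ([0.01, 0.04], [0.02, 0.08]),
        ([0.3], [0.3]),
        ([0.6, 0.9], [1.0, 1.0]),
    ],
)
def test_bonferroni(ps, expected):
    assert bonferroni(ps) == pytest.approx(expected)


def test_bonferroni_rejects_out_of_range():
    with pytest.raises(ValueError):
        bonferroni([0.5, 1.5])
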