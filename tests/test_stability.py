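"""Subject-variance stability statistic, responder stratification, association."""

import numpy as np
import pandas as pd
import pytest

from gutstab import (
    CohortConfig,
    associate_stability_performance,
    between_subject_variance,
    classify_responders,
    combine_kingdoms,
    make_cohort,
    pcoa,
    percent_change_tte,
    resolve_stability,
    simulate_feature_table,
    simulate_performance,
    stability_records,
    subject_variance,
    to_proportions,
)
from gutstab.diversity import bray_curtis_matrix
from gutstab.tables import SampleMetadata, TableError

from .conftest import euclidean_dissimilarity, table_from_array


def _meta(subjects, arms=None, time_points=("pre", "mid")):
    rows = []
    for i, subj in enumerate(subjects):
        arm = (arms or ["HPD"] * len(subjects))[i]
        for t in time_points:
            rows.append({"sample": f"{subj}_{t}", "subject": subj, "arm": arm,
                         "time_point": t})
    return SampleMetadata(pd.DataFrame(rows).set_index("sample"))


# ---------------------------------------------------------------------------
# combine_kingdoms
# ---------------------------------------------------------------------------

def test_single_kingdom_combination_is_normalisation(small_cohort):
    _, tables, _ = small_cohort
    combined = combine_kingdoms([tables["bacterial"]])
    expected = to_proportions(tables["bacterial"])
    assert np.allclose(combined.values(), expected.values())
    assert all(f.startswith("bacterial|") for f in combined.feature_ids)


def test_combined_bray_curtis_is_mean_of_per_kingdom(small_cohort):
    _, tables, _ = small_cohort
    kingdoms = ("bacterial", "FVP", "IV")
    combined = combine_kingdoms([tables[k] for k in kingdoms])
    D_combined = bray_curtis_matrix(combined).values()
    D_each = [
        bray_curtis_matrix(tables[k], on="proportions").values() for k in kingdoms
    ]
    assert np.max(np.abs(D_combined - np.mean(D_each, axis=0))) < 1e-12


def test_samples_missing_from_one_kingdom_are_dropped(small_cohort, caplog):
    _, tables, _ = small_cohort
    partial = tables["FVP"].subset_samples(tables["FVP"].sample_ids[:-2])
    combined = combine_kingdoms([tables["bacterial"], partial])
    assert set(combined.sample_ids) == set(partial.sample_ids)


def test_disjoint_kingdom_samples_rejected(small_cohort):
    _, tables, _ = small_cohort
    a = tables["bacterial"].subset_samples(tables["bacterial"].sample_ids[:3])
    b = tables["FVP"].subset_samples(tables["FVP"].sample_ids[3:6])
    with pytest.raises(TableError, match="share no samples"):
        combine_kingdoms([a, b])


# ---------------------------------------------------------------------------
# subject variance
# ---------------------------------------------------------------------------

def test_identical_samples_have_zero_subject_variance():
    meta = _meta(["A", "B"], time_points=("pre", "mid", "post"))
    table = table_from_array(
        np.tile([[5.0], [3.0], [2.0]], (1, 6)), samples=meta.sample_ids
    )
    scores = pcoa(bray_curtis_matrix(table))
    sv = subject_variance(scores, meta)
    assert np.allclose(sv.values, 0.0, atol=1e-9)


def test_subject_variance_sign_and_order_invariant():
    meta = _meta(["A", "B"])
    D = euclidean_dissimilarity([0.0, 1.0, 5.0, 6.0], ids=meta.sample_ids)
    scores = pcoa(D)
    sv = subject_variance(scores, meta)
    flipped = scores.scores.copy()
    flipped["PC1"] *= -1
    sv_flipped = subject_variance(
        type(scores)(flipped, scores.eigenvalues, scores.proportion_explained), meta
    )
    pd.testing.assert_series_equal(sv, sv_flipped)


def test_subject_variance_on_hand_built_layout():
    # subjects A at coordinates {0, 1}, B at {5, 6}: both PC1 ranges equal the
    # ordination image of a unit gap
    meta = _meta(["A", "B"])
    D = euclidean_dissimilarity([0.0, 1.0, 5.0, 6.0], ids=meta.sample_ids)
    sv = subject_variance(pcoa(D), meta)
    assert sv["A"] == pytest.approx(sv["B"], abs=1e-9)
    assert sv["A"] == pytest.approx(1.0, abs=1e-9)


def test_lone_sample_subject_excluded_with_warning(caplog):
    meta = SampleMetadata(
        pd.DataFrame(
            {
                "subject": ["A", "A", "A", "B"],
                "arm": "HPD",
                "time_point": ["pre", "mid", "post", "pre"],
            },
            index=["A_pre", "A_mid", "A_post", "B_pre"],
        )
    )
    D = euclidean_dissimilarity([0.0, 1.0, 2.0, 7.0], ids=list(meta.frame.index))
    with caplog.at_level("WARNING"):
        sv = subject_variance(pcoa(D), meta)
    assert "B" not in sv.index
    assert "excluded" in caplog.text


# ---------------------------------------------------------------------------
# between-subject variance
# ---------------------------------------------------------------------------

def test_between_subject_variance_brute_force_oracle():
    meta = _meta(["A", "B", "C"], arms=["HPD"] * 3)
    coords = np.array([0.0, 1.0, 10.0, 11.0, 30.0, 31.0])
    scores = pcoa(euclidean_dissimilarity(coords, ids=meta.sample_ids))
    bv = between_subject_variance(scores, meta, "HPD")
    pc1 = scores.pc1()
    for subj in ("A", "B", "C"):
        own = pc1.loc[meta.samples_of(subj)].to_numpy()
        others = np.concatenate(
            [pc1.loc[meta.samples_of(o)].to_numpy() for o in ("A", "B", "C") if o != subj]
        )
        expected = np.mean([abs(x - y) for x in own for y in others])
        assert bv[subj] == pytest.approx(expected, abs=1e-9)
    # well-separated clusters: between >> within
    sv = subject_variance(scores, meta)
    assert (bv > 5 * sv.loc[bv.index]).all()


def test_between_equals_within_scale_for_overlapping_subjects():
    meta = _meta(["A", "B"])
    # both subjects occupy the same two coordinates
    D = euclidean_dissimilarity([0.0, 1.0, 0.0, 1.0], ids=meta.sample_ids)
    scores = pcoa(D)
    bv = between_subject_variance(scores, meta, "HPD")
    sv = subject_variance(scores, meta)
    assert bv["A"] == pytest.approx(bv["B"], abs=1e-9)
    assert bv["A"] == pytest.approx(0.5 * sv["A"], abs=1e-9)  # mean of {0,0,1,1} gaps


def test_between_subject_variance_lone_subject_rejected():
    meta = _meta(["A", "B"], arms=["HPD", "HCD"])
    scores = pcoa(euclidean_dissimilarity([0.0, 1.0, 2.0, 3.0], ids=meta.sample_ids))
    with pytest.raises(TableError, match="fewer than two"):
        between_subject_variance(scores, meta, "HPD")


# ---------------------------------------------------------------------------
# TTE percent change & responders
# ---------------------------------------------------------------------------

def _perf_from_means(means):
    rows = []
    for arm, tte in means.items():
        for tp, val in tte.items():
            rows.append({"subject": f"{arm}_mean", "arm": arm, "time_point": tp,
                         "tte_seconds": val})
    return pd.DataFrame(rows)


def test_percent_change_on_printed_group_means():
    perf = _perf_from_means(
        {
            "HPD": {"pre": 128.3, "mid": 98.4, "post": 125.3},
            "HCD": {"pre": 182.2, "mid": 194.0, "post": 184.0},
        }
    )
    _, per_group = percent_change_tte(perf)
    assert round(per_group.loc["HPD", "mid"], 1) == -23.3
    assert round(per_group.loc["HCD", "mid"], 1) == 6.5
    assert per_group.loc["HPD", "pre"] == 0.0


def test_percent_change_zero_when_mid_equals_pre():
    perf = _perf_from_means({"HPD": {"pre": 100.0, "mid": 100.0, "post": 90.0}})
    per_subject, per_group = percent_change_tte(perf)
    assert per_group.loc["HPD", "mid"] == 0.0
    assert per_subject.loc["HPD_mean", "post"] == pytest.approx(-10.0)


def test_percent_change_missing_baseline_rejected():
    perf = pd.DataFrame(
        [{"subject": "X", "arm": "HPD", "time_point": "mid", "tte_seconds": 50.0}]
    )
    with pytest.raises(TableError, match="pre"):
        percent_change_tte(perf)


def _changes(arm, mids):
    return pd.DataFrame(
        {
            "arm": arm,
            "pre": 0.0,
            "mid": mids,
            "post": 0.0,
        },
        index=[f"s{i}" for i in range(len(mids))],
    )


def test_median_split_halves_an_eight_subject_arm():
    changes = _changes("HPD", [-40, -35, -30, -25, -20, -15, -10, -5])
    out = classify_responders(changes, "HPD", method="median")
    responders = out.index[out["responder"] == "responder"]
    assert len(responders) == 4
    assert set(responders) == {"s0", "s1", "s2", "s3"}  # most-reduced half


def test_residual_and_median_rules_agree_on_hand_example():
    # hand enumeration: mean mid change -21.25, so residuals in the reducing
    # direction pick {-40, -30}; the median (-20) picks the same pair
    changes = pd.DataFrame(
        {"arm": "HPD", "mid": [-40.0, -30.0, -10.0, -5.0]},
        index=[f"s{i}" for i in range(4)],
    )
    for method in ("auto", "median"):
        out = classify_responders(changes, "HPD", method=method)
        responders = set(out.index[out["responder"] == "responder"])
        assert responders == {"s0", "s1"}


def test_identical_changes_unclassifiable():
    changes = _changes("HCD", [5.0, 5.0, 5.0, 5.0])
    with pytest.raises(TableError, match="unclassifiable"):
        classify_responders(changes, "HCD")


def test_uniform_shift_triggers_median_fallback():
    # pre/post anchored at 0 with every mid change on the same side of the
    # pooled regression line: the residual rule marks everyone, so the
    # median split takes over
    changes = _changes("HCD", [20.0, 22.0, 24.0, 26.0])
    out = classify_responders(changes, "HCD")
    assert (out["rule"] == "median-split").all()
    assert set(out.index[out["responder"] == "responder"]) == {"s2", "s3"}


# ---------------------------------------------------------------------------
# association and end-to-end recovery
# ---------------------------------------------------------------------------

def test_stability_linked_cohort_shows_expected_direction():
    config = CohortConfig(seed=21, performance_link=(8.0, 1.0))
    metadata = make_cohort(config)
    tables = [
        simulate_feature_table(metadata, config, k) for k in ("bacterial", "FVP", "IV")
    ]
    perf = simulate_performance(metadata, config)
    records = stability_records(tables, metadata, perf)
    assoc = associate_stability_performance(records)
    # improving HCD subjects hold more stable communities
    assert assoc["HCD"].mean_within_responder < assoc["HCD"].mean_within_nonresponder
    # HPD responders (reduced more) are the turbulent ones
    assert assoc["HPD"].mean_within_responder > assoc["HPD"].mean_within_nonresponder


def test_sigma_zero_responders_partition_by_kappa_rank():
    config = CohortConfig(seed=22, performance_link=(6.0, 0.0), tte_noise=0.0)
    metadata = make_cohort(config)
    kappas = resolve_stability(config, metadata)
    perf = simulate_performance(metadata, config)
    per_subject, _ = percent_change_tte(perf)
    for arm, direction in (("HCD", 1), ("HPD", -1)):
        out = classify_responders(per_subject, arm, method="median")
        ranked = sorted(out.index, key=lambda s: kappas[s])
        half = len(ranked) // 2
        expected = set(ranked[half:]) if direction > 0 else set(ranked[:half])
        assert set(out.index[out["responder"] == "responder"]) == expected


def test_single_arm_association_only_has_that_arm():
    records = pd.DataFrame(
        {
            "arm": "HCD",
            "within_subject_variance": [0.1, 0.2, 0.3, 0.4],
            "responder": ["responder", "responder", "nonresponder", "nonresponder"],
            "mid_percent_change": [9.0, 8.0, 2.0, 1.0],
        },
        index=["a", "b", "c", "d"],
    )
    assoc = associate_stability_performance(records)
    assert set(assoc) == {"HCD"}


def test_empty_responder_class_rejected():
    records = pd.DataFrame(
        {
            "arm": "HCD",
            "within_subject_variance": [0.1, 0.2],
            "responder": ["responder", "responder"],
            "mid_percent_change": [9.0, 8.0],
        },
        index=["a", "b"],
    )
    with pytest.raises(TableError, match="empty responder class"):
        associate_stability_performance(records)
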