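"""Subject-level community stability and its link to endurance performance.

The central statistic is *subject variance*: for each participant, the
range (max - min) of their samples' scores on the first principal
coordinate of the combined-kingdom Bray-Curtis ordination. A small range
means the participant's gut community barely moved across the dietary
period — a stable microbiome. Between-subject variance is the companion
statistic: the mean absolute PC1 distance from a participant's samples to
the samples of the other participants on the same diet arm.

Participants are stratified into responders and nonresponders from their
mid-intervention time-trial-to-exhaustion (TTE) change, and stability is
associated with performance by rank tests within each arm.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .diversity import bray_curtis_matrix, to_proportions
from .ordination import PCoAResult, kruskal_wallis, pcoa
from .tables import DissimilarityMatrix, FeatureTable, SampleMetadata, TableError

__all__ = [
    "combine_kingdoms",
    "subject_variance",
    "between_subject_variance",
    "percent_change_tte",
    "classify_responders",
    "associate_stability_performance",
    "stability_records",
]

logger = logging.getLogger(__name__)

#: arm-characteristic direction of a responder's mid-TTE residual:
#: TTE increased more than expected under the carbohydrate diet, or
#: decreased more than expected under the protein diet.
RESPONDER_DIRECTION = {"HCD": +1.0, "HPD": -1.0}


# ---------------------------------------------------------------------------
# Combined multi-kingdom table
# ---------------------------------------------------------------------------

def combine_kingdoms(tables: Sequence[FeatureTable]) -> FeatureTable:
    """Stack per-kingdom proportion blocks into one combined table.

    Each input table is converted to proportions, its feature ids are
    prefixed with the kingdom label, and the rows are stacked over the
    samples common to all kingdoms. Because every kingdom block of every
    sample sums to 1, the Bray-Curtis dissimilarity of the combined table
    equals the arithmetic mean of the per-kingdom (proportion-based)
    Bray-Curtis dissimilarities — each block contributes denominator 2.
    """
    if not tables:
        raise TableError("no tables to combine")
    shared: set[str] | None = None
    for t in tables:
        shared = set(t.sample_ids) if shared is None else shared & set(t.sample_ids)
    assert shared is not None
    if not shared:
        raise TableError("kingdoms share no samples")
    for t in tables:
        dropped = set(t.sample_ids) - shared
        if dropped:
            logger.warning(
                "combine_kingdoms: dropping %d sample(s) absent from other kingdoms "
                "(%s): %s", len(dropped), t.kingdom, sorted(dropped),
            )
    order = [s for s in tables[0].sample_ids if s in shared]

    blocks = []
    for t in tables:
        props = to_proportions(t).data.loc[:, order]
        props.index = [f"{t.kingdom}|{f}" for f in props.index]
        blocks.append(props)
    combined = pd.concat(blocks, axis=0)
    if combined.index.has_duplicates:
        raise TableError("kingdom-prefixed feature ids collide; kingdom labels must differ")
    mode = "proportions" if len(tables) == 1 else "counts"
    # a multi-kingdom stack sums to n_kingdoms per sample, so it is not a
    # proportion table itself; mark single-kingdom output as proportions
    return FeatureTable(combined, kingdom="combined", level=tables[0].level, mode=mode)


# ---------------------------------------------------------------------------
# Subject variance (the stability statistic)
# ---------------------------------------------------------------------------

def subject_variance(
    scores: PCoAResult, metadata: SampleMetadata
) -> pd.Series:
    """Per-subject range of PC1 scores across that subject's samples.

    The range is invariant to the ordination's sign convention and to the
    ordering of samples. Subjects with fewer than two scored samples are
    excluded with a warning.
    """
    pc1 = scores.pc1()
    out = {}
    for subject in metadata.subjects:
        samples = [s for s in metadata.samples_of(subject) if s in pc1.index]
        if len(samples) < 2:
            logger.warning(
                "subject_variance: subject %r has %d scored sample(s); excluded",
                subject, len(samples),
            )
            continue
        vals = pc1.loc[samples].to_numpy()
        out[subject] = float(vals.max() - vals.min())
    return pd.Series(out, name="within_subject_variance")


def between_subject_variance(
    scores: PCoAResult, metadata: SampleMetadata, arm: str
) -> pd.Series:
    """Mean |PC1| distance from each subject's samples to other same-arm subjects.

    For subject i the value is the average, over pairs (s, t) with s a
    sample of i and t a sample of any *other* subject on the same arm, of
    |PC1(s) - PC1(t)|.
    """
    pc1 = scores.pc1()
    arm_subjects = [s for s in metadata.subjects if metadata.arm_of(s) == arm]
    if len(arm_subjects) < 2:
        raise TableError(f"arm {arm!r} has fewer than two subjects")
    sample_scores = {
        subj: pc1.loc[[s for s in metadata.samples_of(subj) if s in pc1.index]].to_numpy()
        for subj in arm_subjects
    }
    out = {}
    for subj in arm_subjects:
        own = sample_scores[subj]
        others = np.concatenate(
            [sample_scores[o] for o in arm_subjects if o != subj]
        )
        if own.size == 0 or others.size == 0:
            raise TableError(f"subject {subj!r} or its arm peers have no scored samples")
        out[subj] = float(np.mean(np.abs(own[:, None] - others[None, :])))
    return pd.Series(out, name="between_subject_variance")


# ---------------------------------------------------------------------------
# Performance change and responder stratification
# ---------------------------------------------------------------------------

def percent_change_tte(
    perf: pd.DataFrame, *, time_order: Sequence[str] = ("pre", "mid", "post")
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Percent change in TTE from the pre-intervention baseline.

    ``perf`` holds columns ``subject``, ``arm``, ``time_point`` and
    ``tte_seconds`` with one row per subject and time point. Returns

    ``per_subject`` :
        one row per subject, columns = time points, values =
        100*(TTE_t - TTE_pre)/TTE_pre (the pre column is 0 by definition);
    ``per_group`` :
        the same change computed on each arm's mean TTE per time point.
    """
    required = {"subject", "arm", "time_point", "tte_seconds"}
    missing = required - set(perf.columns)
    if missing:
        raise TableError(f"performance table missing columns: {sorted(missing)}")
    if (perf["tte_seconds"] <= 0).any():
        raise TableError("TTE values must be positive")
    baseline_label = time_order[0]

    wide = perf.pivot_table(
        index="subject", columns="time_point", values="tte_seconds", aggfunc="first"
    )
    if baseline_label not in wide.columns or wide[baseline_label].isna().any():
        bad = (
            wide.index[wide[baseline_label].isna()].tolist()
            if baseline_label in wide.columns
            else wide.index.tolist()
        )
        raise TableError(f"missing {baseline_label!r} TTE for subjects: {bad}")
    cols = [t for t in time_order if t in wide.columns]
    per_subject = 100.0 * wide[cols].sub(wide[baseline_label], axis=0).div(
        wide[baseline_label], axis=0
    )
    arm_of = perf.drop_duplicates("subject").set_index("subject")["arm"]
    per_subject.insert(0, "arm", arm_of.reindex(per_subject.index))

    group_means = perf.pivot_table(
        index="arm", columns="time_point", values="tte_seconds", aggfunc="mean"
    )
    per_group = 100.0 * group_means[cols].sub(group_means[baseline_label], axis=0).div(
        group_means[baseline_label], axis=0
    )
    return per_subject, per_group


def classify_responders(
    changes: pd.DataFrame,
    arm: str,
    *,
    time_order: Sequence[str] = ("pre", "mid", "post"),
    mid_label: str = "mid",
    method: str = "auto",
) -> pd.DataFrame:
    """Split an arm's subjects into responders and nonresponders.

    A least-squares line of percent change against time-point index is
    fitted across all of the arm's (subject, time point) observations; a
    subject is a responder when its mid-intervention residual falls in the
    arm-characteristic direction (above the line for HCD, below for HPD).
    When that rule marks everyone or no one — which happens whenever the
    whole arm shifts together, since the fitted line then passes through
    the arm's own mean — the split falls back to the median of the
    per-subject mid changes (strictly above = responder for HCD, strictly
    below for HPD; the median subject of an odd-sized arm is a
    nonresponder). ``method`` selects the rule: ``"auto"`` (residual with
    median fallback, the default), ``"residual"`` (no fallback) or
    ``"median"`` (median split directly, which halves an even-sized arm
    with distinct changes into equal classes).
    """
    if method not in ("auto", "residual", "median"):
        raise TableError(f"unknown method {method!r}")
    if arm not in RESPONDER_DIRECTION:
        raise TableError(
            f"unknown arm {arm!r}; expected one of {sorted(RESPONDER_DIRECTION)}"
        )
    arm_changes = changes[changes["arm"] == arm] if "arm" in changes.columns else changes
    time_cols = [t for t in time_order if t in arm_changes.columns]
    if mid_label not in time_cols:
        raise TableError(f"no {mid_label!r} column in changes table")
    if len(arm_changes) < 2:
        raise TableError(f"arm {arm!r} has fewer than two subjects")
    mid = arm_changes[mid_label].astype(float)
    if mid.nunique() == 1:
        raise TableError(
            f"all subjects in arm {arm!r} share the same mid change; unclassifiable"
        )

    direction = RESPONDER_DIRECTION[arm]
    # pooled regression of change on time index, all subjects and time points;
    # with a single time column the line degenerates to the arm mean at mid
    if len(time_cols) < 2:
        fitted_mid = float(mid.mean())
    else:
        x = np.concatenate(
            [np.full(len(arm_changes), i, dtype=float) for i, _ in enumerate(time_cols)]
        )
        y = np.concatenate([arm_changes[t].to_numpy(dtype=float) for t in time_cols])
        slope, intercept = np.polyfit(x, y, 1)
        fitted_mid = intercept + slope * time_cols.index(mid_label)
    residuals = mid - fitted_mid
    is_responder = direction * residuals > 0
    rule = "residual"

    degenerate = is_responder.all() or not is_responder.any()
    if method == "median" or (method == "auto" and degenerate):
        median = float(np.median(mid))
        is_responder = direction * (mid - median) > 0
        rule = "median-split"
    elif method == "residual" and degenerate:
        logger.warning(
            "classify_responders: residual rule yields a one-sided split for arm %r",
            arm,
        )

    return pd.DataFrame(
        {
            "arm": arm,
            "mid_percent_change": mid,
            "residual": residuals,
            "responder": np.where(is_responder, "responder", "nonresponder"),
            "rule": rule,
        },
        index=arm_changes.index,
    )


# ---------------------------------------------------------------------------
# Putting it together
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ArmAssociation:
    """Stability-vs-performance association within one diet arm."""

    arm: str
    kw_h: float
    kw_p: float
    spearman_rho: float
    spearman_p: float
    mean_within_responder: float
    mean_within_nonresponder: float

    def as_dict(self) -> dict:
        return {
            "arm": self.arm,
            "kw_h": self.kw_h,
            "kw_p": self.kw_p,
            "spearman_rho": self.spearman_rho,
            "spearman_p": self.spearman_p,
            "mean_within_responder": self.mean_within_responder,
            "mean_within_nonresponder": self.mean_within_nonresponder,
        }


def associate_stability_performance(records: pd.DataFrame) -> dict[str, ArmAssociation]:
    """Per arm: rank tests linking within-subject variance to performance.

    ``records`` holds one row per subject with columns ``arm``,
    ``within_subject_variance``, ``responder`` and ``mid_percent_change``.
    For each arm a Kruskal-Wallis test compares within-subject variance
    between responder classes, and a Spearman correlation relates
    within-subject variance to the mid TTE change.
    """
    required = {"arm", "within_subject_variance", "responder", "mid_percent_change"}
    missing = required - set(records.columns)
    if missing:
        raise TableError(f"stability records missing columns: {sorted(missing)}")
    out = {}
    for arm, block in records.groupby("arm"):
        classes = block["responder"]
        if classes.nunique() < 2:
            raise TableError(f"arm {arm!r} has an empty responder class")
        h, p = kruskal_wallis(block["within_subject_variance"], classes)
        rho, rho_p = spearmanr(
            block["within_subject_variance"], block["mid_percent_change"]
        )
        out[str(arm)] = ArmAssociation(
            arm=str(arm),
            kw_h=h,
            kw_p=p,
            spearman_rho=float(rho),
            spearman_p=float(rho_p),
            mean_within_responder=float(
                block.loc[classes == "responder", "within_subject_variance"].mean()
            ),
            mean_within_nonresponder=float(
                block.loc[classes == "nonresponder", "within_subject_variance"].mean()
            ),
        )
    return out


def stability_records(
    tables: Sequence[FeatureTable],
    metadata: SampleMetadata,
    perf: pd.DataFrame | None = None,
    *,
    per_arm_ordination: bool = True,
) -> pd.DataFrame:
    """Full stability workup: combine kingdoms, ordinate, score each subject.

    For each diet arm (the default; set ``per_arm_ordination=False`` for a
    single joint ordination) the combined-kingdom Bray-Curtis matrix of
    that arm's samples is ordinated by PCoA and each subject receives its
    within-subject PC1 range and between-subject mean |PC1| distance.
    When a performance table is supplied, mid TTE percent change and
    responder status are attached.
    """
    combined = combine_kingdoms(tables)
    meta = metadata.subset([s for s in combined.sample_ids])

    change_table = None
    if perf is not None:
        change_table, _ = percent_change_tte(perf, time_order=metadata.time_order)

    frames = []
    arms = meta.arms if per_arm_ordination else [None]
    for arm in arms:
        if arm is None:
            arm_samples = combined.sample_ids
        else:
            arm_samples = [
                s for s in combined.sample_ids if meta.frame.loc[s, "arm"] == arm
            ]
        sub_table = combined.subset_samples(arm_samples)
        sub_meta = meta.subset(arm_samples)
        D = _combined_bray_curtis(sub_table)
        scores = pcoa(D)
        within = subject_variance(scores, sub_meta)
        arm_frames = []
        for a in sub_meta.arms:
            between = between_subject_variance(scores, sub_meta, a)
            rec = pd.DataFrame(
                {
                    "arm": a,
                    "within_subject_variance": within.reindex(between.index),
                    "between_subject_variance": between,
                }
            )
            arm_frames.append(rec)
        frames.append(pd.concat(arm_frames))
    records = pd.concat(frames)
    records.index.name = "subject"

    if change_table is not None:
        responder_frames = [
            classify_responders(change_table, a, time_order=metadata.time_order)
            for a in records["arm"].unique()
        ]
        responders = pd.concat(responder_frames)
        records = records.join(
            responders[["mid_percent_change", "responder"]], how="left"
        )
    return records


def _combined_bray_curtis(combined: FeatureTable) -> DissimilarityMatrix:
    # combined tables are stacks of proportion blocks: use values as given
    return bray_curtis_matrix(combined, on="counts")
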