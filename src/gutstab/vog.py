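"""Viral orthologous group (VOG) gene analysis.

Covers the hierarchical best-hit disambiguation applied when one query
sequence aligns to multiple VOG targets, per-sample functional richness
and Simpson dominance of VOG abundance profiles with percent change from
each subject's pre-intervention baseline, and grouping of VOG genes into
high-level functional classes.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

from .diversity import richness, simpson_dominance, to_proportions
from .tables import FeatureTable, SampleMetadata, TableError

__all__ = [
    "disambiguate_hits",
    "functional_richness",
    "functional_dominance",
    "percent_change_from_baseline",
    "group_functional_classes",
    "DEFAULT_CLASS_MAPPING_EXAMPLE",
]

_HIT_COLUMNS = ("query", "target", "status", "v_score", "e_score")
_STATUSES = ("actual", "putative")

#: illustrative high-level class labels for VOG genes; real analyses
#: supply their own two-column mapping file
DEFAULT_CLASS_MAPPING_EXAMPLE = ("structure", "metabolism", "replication", "unclassified")


def disambiguate_hits(hits: pd.DataFrame) -> pd.DataFrame:
    """Select one best VOG hit per query by the hierarchical preference rule.

    Per query: (1) "actual" classifications beat "putative"; (2) among the
    survivors the greatest V.score wins; (3) V.score ties go to the lowest
    E.score; (4) any remaining tie breaks on the lexicographically
    smallest target id, which makes the selection a deterministic function
    of the hit *set*, independent of input row order.
    """
    missing = set(_HIT_COLUMNS) - set(hits.columns)
    if missing:
        raise TableError(f"hit table missing columns: {sorted(missing)}")
    bad_status = set(hits["status"].unique()) - set(_STATUSES)
    if bad_status:
        raise TableError(
            f"malformed classification status {sorted(bad_status)}; "
            f"expected one of {_STATUSES}"
        )
    if (hits["e_score"] <= 0).any():
        raise TableError("E.scores must be > 0")

    ranked = hits.assign(
        _status_rank=(hits["status"] != "actual").astype(int),
        _neg_v=-hits["v_score"].astype(float),
    ).sort_values(
        ["query", "_status_rank", "_neg_v", "e_score", "target"],
        kind="mergesort",
    )
    best = ranked.groupby("query", sort=True).head(1)
    return (
        best.drop(columns=["_status_rank", "_neg_v"])
        .reset_index(drop=True)
    )


def functional_richness(table: FeatureTable) -> pd.Series:
    """Per-sample count of VOG genes with non-zero abundance."""
    values = table.values()
    return pd.Series(
        {s: richness(values[:, j]) for j, s in enumerate(table.sample_ids)},
        name="richness",
    )


def functional_dominance(table: FeatureTable) -> pd.Series:
    """Per-sample Simpson dominance of the VOG proportion vector."""
    props = to_proportions(table).values()
    return pd.Series(
        {s: simpson_dominance(props[:, j]) for j, s in enumerate(table.sample_ids)},
        name="dominance",
    )


def percent_change_from_baseline(
    series: pd.Series, metadata: SampleMetadata
) -> pd.Series:
    """Percent change of a per-sample metric vs the subject's pre sample.

    For each sample at time t: 100 * (value_t - value_pre) / value_pre,
    where value_pre is the same subject's metric at the first time point.
    Subjects whose baseline metric is missing or zero raise an error.
    """
    baseline_label = metadata.time_order[0]
    baseline: dict[str, float] = {}
    for subj in metadata.subjects:
        pre_samples = [
            s
            for s in metadata.samples_of(subj)
            if metadata.frame.loc[s, "time_point"] == baseline_label and s in series.index
        ]
        if not pre_samples:
            raise TableError(f"subject {subj!r} has no {baseline_label!r} sample")
        val = float(series.loc[pre_samples[0]])
        if val == 0 or np.isnan(val):
            raise TableError(
                f"subject {subj!r} has zero/undefined baseline {series.name}; "
                "percent change undefined"
            )
        baseline[subj] = val

    out = {}
    for sample in series.index:
        if sample not in metadata.frame.index:
            continue
        subj = metadata.frame.loc[sample, "subject"]
        out[sample] = 100.0 * (float(series.loc[sample]) - baseline[subj]) / baseline[subj]
    return pd.Series(out, name=f"{series.name}_pct_change")


def group_functional_classes(
    table: FeatureTable, mapping: Mapping[str, str]
) -> tuple[FeatureTable, pd.DataFrame]:
    """Collapse VOG genes into high-level functional classes.

    Genes absent from ``mapping`` are pooled under "unclassified". Total
    abundance per sample is conserved exactly. Returns the class-level
    table and its per-sample class proportions.
    """
    if not mapping:
        raise TableError("empty class mapping")
    classes = pd.Series(
        {f: mapping.get(f, "unclassified") for f in table.feature_ids}
    )
    grouped = table.data.groupby(classes, sort=True).sum()
    grouped.index.name = "class"
    class_table = FeatureTable(
        grouped, kingdom=table.kingdom, level="functional_class", mode=table.mode
    )
    sums = grouped.sum(axis=0)
    if (sums == 0).any():
        raise TableError(
            f"all-zero sample columns: {sums.index[sums == 0].tolist()}"
        )
    proportions = grouped / sums
    return class_table, proportions
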