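"""End-to-end orchestration: simulate -> diversity -> ordination ->
inference -> stability -> responders -> association -> report.

`run_pipeline` executes the full analysis from a :class:`RunConfig` that
either names input files on disk or embeds a simulation block, writes
every artifact as TSV/JSON under an output directory, and finishes with a
checksum manifest and a human-readable summary. Identical configuration
and seed produce byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import io as gio
from .diversity import alpha_diversity_table, bray_curtis_matrix
from .ordination import kruskal_wallis, pcoa, permanova
from .simulate import KINGDOMS, CohortConfig, make_cohort, simulate_feature_table, \
    simulate_performance, simulate_vog_hits
from .stability import associate_stability_performance, percent_change_tte, \
    stability_records
from .tables import FeatureTable, SampleMetadata
from .vog import disambiguate_hits, functional_dominance, functional_richness, \
    percent_change_from_baseline

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]

logger = logging.getLogger(__name__)

TAXONOMIC_KINGDOMS = ("bacterial", "FVP", "IV")


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and the underlying cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass(frozen=True)
class RunConfig:
    """Inputs, analysis settings and output location for one pipeline run.

    Exactly one of ``input_paths`` (a mapping with keys ``metadata``,
    ``performance`` and one path per kingdom table) or ``simulation``
    (a :class:`CohortConfig`) must be provided.
    """

    out_dir: str | Path
    simulation: CohortConfig | None = None
    input_paths: Mapping[str, str] | None = None
    kingdoms: Sequence[str] = TAXONOMIC_KINGDOMS
    n_perm: int = 999
    seed: int = 0
    bray_curtis_on: str = "counts"

    def __post_init__(self) -> None:
        if (self.simulation is None) == (self.input_paths is None):
            raise ValueError(
                "exactly one of `simulation` and `input_paths` must be given"
            )


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and return the manifest (artifact -> sha256).

    On a stage failure, artifacts written so far are kept, a ``FAILED``
    marker file naming the stage is dropped in the output directory, and
    :class:`PipelineError` is raised.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = config.seed
    artifacts: list[Path] = []
    stage = "setup"

    def track(path: Path) -> Path:
        artifacts.append(path)
        return path

    try:
        # ------------------------------------------------------------------
        stage = "inputs"
        t0 = time.perf_counter()
        if config.simulation is not None:
            sim = config.simulation
            metadata = make_cohort(sim)
            tables = {
                k: simulate_feature_table(metadata, sim, k) for k in config.kingdoms
            }
            vog_table = (
                simulate_feature_table(metadata, sim, "VOG-abundance")
                if "VOG-abundance" in sim.n_features
                else None
            )
            perf = simulate_performance(metadata, sim)
            vog_hits = simulate_vog_hits(50, seed=sim.seed)
            gio.write_metadata(metadata, track(out / "metadata.tsv"), seed=seed)
            gio.write_performance(perf, track(out / "performance.tsv"), seed=seed)
            for k, t in tables.items():
                gio.write_feature_table(
                    t, track(out / f"counts_{k}.tsv"), seed=seed
                )
            if vog_table is not None:
                gio.write_feature_table(
                    vog_table, track(out / "counts_VOG-abundance.tsv"), seed=seed
                )
            gio.write_vog_hits(vog_hits, track(out / "vog_hits.tsv"), seed=seed)
        else:
            paths = dict(config.input_paths or {})
            metadata = gio.read_metadata(paths["metadata"])
            perf = (
                gio.read_performance(paths["performance"])
                if "performance" in paths
                else None
            )
            tables = {
                k: gio.read_feature_table(paths[k], kingdom=k)
                for k in config.kingdoms
            }
            vog_table = (
                gio.read_feature_table(paths["VOG-abundance"], kingdom="VOG-abundance")
                if "VOG-abundance" in paths
                else None
            )
            vog_hits = gio.read_vog_hits(paths["vog_hits"]) if "vog_hits" in paths else None
        logger.info("stage inputs done in %.2fs", time.perf_counter() - t0)

        # ------------------------------------------------------------------
        stage = "alpha-diversity"
        t0 = time.perf_counter()
        alpha_frames = []
        for k, t in tables.items():
            a = alpha_diversity_table(t)
            a.insert(0, "kingdom", k)
            alpha_frames.append(a)
        alpha = pd.concat(alpha_frames)
        with open(track(out / "alpha_diversity.tsv"), "w") as fh:
            fh.write(f"# seed: {seed}\n")
            alpha.to_csv(fh, sep="\t")
        logger.info("stage alpha-diversity done in %.2fs", time.perf_counter() - t0)

        # ------------------------------------------------------------------
        stage = "beta-diversity"
        t0 = time.perf_counter()
        matrices = {}
        for k, t in tables.items():
            D = bray_curtis_matrix(t, on=config.bray_curtis_on)
            matrices[k] = D
            gio.write_dissimilarity(D, track(out / f"braycurtis_{k}.tsv"), seed=seed)
        logger.info("stage beta-diversity done in %.2fs", time.perf_counter() - t0)

        # ------------------------------------------------------------------
        stage = "ordination"
        t0 = time.perf_counter()
        for k, D in matrices.items():
            scores = pcoa(D)
            with open(track(out / f"pcoa_scores_{k}.tsv"), "w") as fh:
                fh.write(f"# seed: {seed}\n")
                scores.scores.to_csv(fh, sep="\t")
        logger.info("stage ordination done in %.2fs", time.perf_counter() - t0)

        # ------------------------------------------------------------------
        stage = "permutation-tests"
        t0 = time.perf_counter()
        test_results: dict[str, dict] = {}
        subject_of = metadata.frame["subject"].to_dict()
        time_of = metadata.frame["time_point"].to_dict()
        for k, D in matrices.items():
            for arm in metadata.arms:
                arm_samples = [
                    s for s in D.sample_ids if metadata.frame.loc[s, "arm"] == arm
                ]
                sub = D.submatrix(arm_samples)
                res = permanova(
                    sub,
                    {s: time_of[s] for s in arm_samples},
                    strata={s: subject_of[s] for s in arm_samples},
                    n_perm=config.n_perm,
                    seed=seed,
                )
                test_results[f"permanova_time_{k}_{arm}"] = res.as_dict()
        for k, t in tables.items():
            a = alpha_diversity_table(t)
            arm_labels = [metadata.frame.loc[s, "arm"] for s in a.index]
            h, p = kruskal_wallis(a["fisher_alpha"].fillna(0.0), arm_labels)
            test_results[f"kw_fisher_alpha_{k}_by_arm"] = {"h": h, "p": p}
        gio.write_json(test_results, track(out / "inference.json"))
        logger.info("stage permutation-tests done in %.2fs", time.perf_counter() - t0)

        # ------------------------------------------------------------------
        stage = "stability"
        t0 = time.perf_counter()
        records = stability_records(
            [tables[k] for k in config.kingdoms if k in TAXONOMIC_KINGDOMS],
            metadata,
            perf,
        )
        with open(track(out / "stability_records.tsv"), "w") as fh:
            fh.write(f"# seed: {seed}\n")
            records.to_csv(fh, sep="\t")
        logger.info("stage stability done in %.2fs", time.perf_counter() - t0)

        # ------------------------------------------------------------------
        stage = "association"
        t0 = time.perf_counter()
        association = {}
        if perf is not None:
            association = {
                arm: assoc.as_dict()
                for arm, assoc in associate_stability_performance(records).items()
            }
            gio.write_json(association, track(out / "association.json"))
        logger.info("stage association done in %.2fs", time.perf_counter() - t0)

        # ------------------------------------------------------------------
        stage = "vog"
        t0 = time.perf_counter()
        if vog_hits is not None:
            best = disambiguate_hits(vog_hits)
            gio.write_vog_hits(best, track(out / "vog_best_hits.tsv"), seed=seed)
        if vog_table is not None:
            rich = functional_richness(vog_table)
            dom = functional_dominance(vog_table)
            func = pd.DataFrame({"richness": rich, "dominance": dom})
            func["richness_pct_change"] = percent_change_from_baseline(rich, metadata)
            func["dominance_pct_change"] = percent_change_from_baseline(dom, metadata)
            func.index.name = "sample"
            with open(track(out / "vog_functional_metrics.tsv"), "w") as fh:
                fh.write(f"# seed: {seed}\n")
                func.to_csv(fh, sep="\t")
        logger.info("stage vog done in %.2fs", time.perf_counter() - t0)

        # ------------------------------------------------------------------
        stage = "report"
        t0 = time.perf_counter()
        lines = [f"gutstab pipeline summary (seed {seed})", ""]
        lines.append(f"samples: {len(metadata.sample_ids)}  subjects: {len(metadata.subjects)}")
        if perf is not None:
            _, per_group = percent_change_tte(perf, time_order=metadata.time_order)
            mid = metadata.time_order[1]
            for arm in per_group.index:
                lines.append(
                    f"arm {arm}: mean TTE change at {mid} = "
                    f"{per_group.loc[arm, mid]:+.1f}%"
                )
        for name, res in test_results.items():
            if "p_value" in res:
                lines.append(
                    f"{name}: R2={res['r_squared']:.3f} p={res['p_value']:.4f}"
                )
        for arm, a in association.items():
            lines.append(
                f"stability vs performance [{arm}]: KW p={a['kw_p']:.4f}, "
                f"Spearman rho={a['spearman_rho']:+.3f}; within-subject variance "
                f"responders {a['mean_within_responder']:.3f} vs "
                f"nonresponders {a['mean_within_nonresponder']:.3f}"
            )
        summary_path = track(out / "summary.txt")
        summary_path.write_text("\n".join(lines) + "\n")
        logger.info("stage report done in %.2fs", time.perf_counter() - t0)

        # ------------------------------------------------------------------
        stage = "manifest"
        manifest = {
            "seed": seed,
            "artifacts": {p.name: _checksum(p) for p in sorted(set(artifacts))},
        }
        gio.write_json(manifest, out / "manifest.json")
        return manifest

    except Exception as exc:  # noqa: BLE001 - rewrap with the failing stage
        (out / "FAILED").write_text(f"stage: {stage}\ncause: {exc}\n")
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError(stage, exc) from exc
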