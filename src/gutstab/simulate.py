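"""Synthetic longitudinal multi-kingdom cohort generator.

Emulates the statistical structure of a two-arm dietary crossover-free
(parallel-group) athlete study: 8 subjects per diet arm sampled at three
time points (pre/mid/post intervention) across three microbial
compartments — bacteria, free viral particles (FVP) and inducible viruses
(IV) — plus viral functional-gene (VOG) abundance tables and alignment
hit tables.

The generative model:

* each subject draws a baseline composition from a shared symmetric
  Dirichlet (low concentration => strongly subject-specific communities);
* each time point's composition is a Dirichlet draw centred on the
  subject's baseline with concentration kappa_i — the subject's temporal
  stability: large kappa pins the community to its baseline, small kappa
  lets it wander;
* the diet arm's effect multiplies designated features at the mid time
  point only (compositions revert at post), then renormalises;
* counts are multinomial at a per-kingdom library size;
* time-trial-to-exhaustion (TTE) performance: pre and post vary tightly
  around a subject baseline, while the mid percent change equals the
  arm's mean effect plus beta * (log kappa_i - arm mean log kappa) plus
  Gaussian noise, so stability and performance are linked with slope
  beta, without moving the arm's mean away from its prescribed effect.

Everything is a pure function of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .tables import FeatureTable, SampleMetadata

__all__ = [
    "CohortConfig",
    "VOGHitParams",
    "ConfigError",
    "make_cohort",
    "resolve_stability",
    "simulate_feature_table",
    "simulate_performance",
    "simulate_vog_hits",
    "simulate_study",
]

KINGDOMS = ("bacterial", "FVP", "IV", "VOG-abundance")

#: named "story" features per kingdom; remaining features are anonymous
_STORY_FEATURES = {
    "bacterial": ("Leuconostoc", "Ruminococcus", "Collinsella", "Bifidobacterium"),
    "FVP": ("Sk1virus", "Schizot4virus", "Cc31virus", "Chlorovirus"),
    "IV": ("Sk1virus", "Schizot4virus", "L5virus", "Cafeteriavirus"),
    "VOG-abundance": (),
}


class ConfigError(ValueError):
    """Raised when a cohort configuration is invalid; names the field."""


@dataclass(frozen=True)
class CohortConfig:
    """Study-design and generative parameters for a synthetic cohort.

    Defaults encode the emulated study conditions: 8 athletes per arm on
    isocaloric high-protein (HPD) or high-carbohydrate (HCD) diets,
    sampled pre/mid/post intervention. Library sizes for the viral
    compartments follow the reported per-sample read means (FVP 234, IV
    187); the bacterial and VOG defaults (30000 and 20000) are this
    package's own choices of a plausible amplicon / mapped-gene depth.
    TTE baselines per arm (mean, SD seconds) and the arm mean mid-TTE
    effects (-23.3% HPD, +6.5% HCD) follow the emulated study's printed
    group values.
    """

    n_subjects_per_arm: int = 8
    arms: tuple[str, ...] = ("HPD", "HCD")
    time_points: tuple[str, ...] = ("pre", "mid", "post")
    library_size: Mapping[str, int] = field(
        default_factory=lambda: {
            "bacterial": 30000, "FVP": 234, "IV": 187, "VOG-abundance": 20000
        }
    )
    n_features: Mapping[str, int] = field(
        default_factory=lambda: {
            "bacterial": 80, "FVP": 40, "IV": 40, "VOG-abundance": 200
        }
    )
    #: per-subject temporal concentration kappa. None => log-spaced over
    #: ``kappa_range`` across each arm's subjects; a scalar broadcasts; a
    #: sequence of length n_subjects_per_arm applies per arm in subject
    #: order; a mapping assigns subjects directly.
    stability: float | Sequence[float] | Mapping[str, float] | None = None
    kappa_range: tuple[float, float] = (10.0, 300.0)
    #: baseline subject-specificity: symmetric Dirichlet concentration per
    #: feature for the baseline draw (smaller => more individual)
    subject_specificity: float = 0.3
    #: per-arm multiplicative shifts applied to named features at mid only
    diet_effect: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {
            "HPD": {"Sk1virus": 4.0, "Leuconostoc": 3.0},
            "HCD": {"Ruminococcus": 2.0, "Collinsella": 2.0},
        }
    )
    #: (beta, sigma): percent mid-TTE change per unit centred log-kappa,
    #: and the Gaussian noise SD on that change (percent points)
    performance_link: tuple[float, float] = (6.0, 3.0)
    #: per-arm mean TTE percent change at mid
    arm_effect: Mapping[str, float] = field(
        default_factory=lambda: {"HPD": -23.3, "HCD": 6.5}
    )
    #: per-arm (mean, SD) of baseline TTE seconds
    tte_baseline: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {"HPD": (128.3, 29.3), "HCD": (182.2, 44.4)}
    )
    #: SD (percent) of pre/post TTE variation about the subject baseline
    tte_noise: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects_per_arm < 2:
            raise ConfigError(
                f"n_subjects_per_arm must be >= 2, got {self.n_subjects_per_arm}"
            )
        if len(self.time_points) != 3:
            raise ConfigError(
                f"time_points must name exactly 3 time points, got {self.time_points}"
            )
        if len(set(self.arms)) != len(self.arms) or not self.arms:
            raise ConfigError(f"arms must be distinct and nonempty, got {self.arms}")
        for k, v in self.library_size.items():
            if v <= 0:
                raise ConfigError(f"library_size[{k!r}] must be > 0, got {v}")
        for k, v in self.n_features.items():
            if v < 1:
                raise ConfigError(f"n_features[{k!r}] must be >= 1, got {v}")
        for arm, effects in self.diet_effect.items():
            for feat, mult in effects.items():
                if mult <= 0:
                    raise ConfigError(
                        f"diet_effect[{arm!r}][{feat!r}] must be > 0, got {mult}"
                    )
        lo, hi = self.kappa_range
        if not (0 < lo <= hi):
            raise ConfigError(f"kappa_range must satisfy 0 < lo <= hi, got {self.kappa_range}")
        if self.subject_specificity <= 0:
            raise ConfigError(
                f"subject_specificity must be > 0, got {self.subject_specificity}"
            )
        if self.performance_link[1] < 0:
            raise ConfigError(
                f"performance_link noise sigma must be >= 0, got {self.performance_link[1]}"
            )
        if self.tte_noise < 0:
            raise ConfigError(f"tte_noise must be >= 0, got {self.tte_noise}")
        if isinstance(self.stability, Mapping):
            bad = {s: k for s, k in self.stability.items() if k <= 0}
            if bad:
                raise ConfigError(f"stability: kappa must be > 0, offenders: {bad}")
        elif isinstance(self.stability, (int, float)) and self.stability is not None:
            if self.stability <= 0:
                raise ConfigError(f"stability: kappa must be > 0, got {self.stability}")
        elif self.stability is not None:
            vals = list(self.stability)
            if len(vals) != self.n_subjects_per_arm:
                raise ConfigError(
                    "stability: sequence length must equal n_subjects_per_arm "
                    f"({self.n_subjects_per_arm}), got {len(vals)}"
                )
            if any(k <= 0 for k in vals):
                raise ConfigError(f"stability: kappa must be > 0, got {vals}")


@dataclass(frozen=True)
class VOGHitParams:
    """Settings for synthetic VOG alignment hit tables."""

    max_hits_per_query: int = 4
    p_actual: float = 0.6
    n_targets: int = 50

    def __post_init__(self) -> None:
        if self.max_hits_per_query < 1:
            raise ConfigError(
                f"max_hits_per_query must be >= 1, got {self.max_hits_per_query}"
            )
        if not 0.0 <= self.p_actual <= 1.0:
            raise ConfigError(f"p_actual must be in [0, 1], got {self.p_actual}")


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _rng(config_seed: int, *stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(config_seed, spawn_key=stream))


def _subject_ids(config: CohortConfig) -> dict[str, list[str]]:
    out: dict[str, list[str]] = {}
    counter = 1
    for arm in config.arms:
        out[arm] = [f"S{counter + i:02d}" for i in range(config.n_subjects_per_arm)]
        counter += config.n_subjects_per_arm
    return out


def _feature_ids(config: CohortConfig, kingdom: str) -> list[str]:
    n = config.n_features.get(kingdom)
    if n is None:
        raise ConfigError(f"n_features has no entry for kingdom {kingdom!r}")
    story = list(_STORY_FEATURES.get(kingdom, ()))[:n]
    prefix = {"bacterial": "g", "FVP": "v", "IV": "iv", "VOG-abundance": "VOG"}.get(
        kingdom, "f"
    )
    anon = [f"{prefix}{i:04d}" for i in range(1, n - len(story) + 1)]
    return story + anon


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def make_cohort(config: CohortConfig) -> SampleMetadata:
    """Build the sample sheet: one record per subject x time point.

    Sample ids are ``<subject>_<time>``; the same sheet serves every
    kingdom. Deterministic: a pure function of the configuration.
    """
    rows = []
    for arm, subjects in _subject_ids(config).items():
        for subj in subjects:
            for tp in config.time_points:
                rows.append(
                    {"sample": f"{subj}_{tp}", "subject": subj, "arm": arm,
                     "time_point": tp}
                )
    frame = pd.DataFrame(rows).set_index("sample")
    return SampleMetadata(frame, time_order=config.time_points)


def resolve_stability(config: CohortConfig, metadata: SampleMetadata) -> dict[str, float]:
    """Resolve the per-subject temporal concentration kappa_i.

    With ``config.stability`` unset, kappa is log-spaced over
    ``config.kappa_range`` across each arm's subjects in id order, giving
    every arm the same spread of stable and unstable individuals.
    """
    spec = config.stability
    subjects_by_arm: dict[str, list[str]] = {}
    for subj in metadata.subjects:
        subjects_by_arm.setdefault(metadata.arm_of(subj), []).append(subj)

    out: dict[str, float] = {}
    if isinstance(spec, Mapping):
        missing = [s for s in metadata.subjects if s not in spec]
        if missing:
            raise ConfigError(f"stability: missing kappa for subjects {missing}")
        return {s: float(spec[s]) for s in metadata.subjects}
    for arm, subjects in subjects_by_arm.items():
        if spec is None:
            lo, hi = config.kappa_range
            kappas = np.exp(np.linspace(np.log(lo), np.log(hi), len(subjects)))
        elif isinstance(spec, (int, float)):
            kappas = np.full(len(subjects), float(spec))
        else:
            kappas = np.asarray(list(spec), dtype=float)
            if kappas.size != len(subjects):
                raise ConfigError(
                    f"stability: sequence length {kappas.size} != subjects in arm "
                    f"{arm!r} ({len(subjects)})"
                )
        out.update({s: float(k) for s, k in zip(sorted(subjects), kappas)})
    return out


def simulate_feature_table(
    metadata: SampleMetadata, config: CohortConfig, kingdom: str
) -> FeatureTable:
    """Dirichlet-multinomial longitudinal count table for one kingdom.

    Subject baselines come from a shared symmetric Dirichlet
    (``subject_specificity`` per feature); each time point redraws the
    composition from Dirichlet(kappa_i * baseline); the arm's diet-effect
    multipliers act on designated features at the mid time point only,
    after which the composition is renormalised; counts are multinomial
    at the kingdom's library size.
    """
    if kingdom not in KINGDOMS:
        raise ConfigError(f"unknown kingdom {kingdom!r}; expected one of {KINGDOMS}")
    features = _feature_ids(config, kingdom)
    n_feat = len(features)
    library = config.library_size.get(kingdom)
    if library is None:
        raise ConfigError(f"library_size has no entry for kingdom {kingdom!r}")
    kappas = resolve_stability(config, metadata)
    k_idx = KINGDOMS.index(kingdom)
    mid_label = metadata.time_order[1]

    columns: dict[str, np.ndarray] = {}
    for si, subj in enumerate(metadata.subjects):
        rng = _rng(config.seed, 1, k_idx, si)
        arm = metadata.arm_of(subj)
        baseline = rng.dirichlet(np.full(n_feat, config.subject_specificity))
        baseline = np.maximum(baseline, 1e-12)
        baseline /= baseline.sum()
        kappa = kappas[subj]
        effects = config.diet_effect.get(arm, {})
        mult = np.ones(n_feat)
        for feat, m in effects.items():
            if feat in features:
                mult[features.index(feat)] = m
        subj_samples = {
            metadata.frame.loc[s, "time_point"]: s for s in metadata.samples_of(subj)
        }
        for tp in metadata.time_order:
            if tp not in subj_samples:
                continue
            comp = rng.dirichlet(kappa * baseline)
            if tp == mid_label:
                comp = comp * mult
                comp = comp / comp.sum()
            counts = rng.multinomial(library, comp)
            columns[subj_samples[tp]] = counts

    data = pd.DataFrame(columns, index=pd.Index(features, name="feature"))
    data = data.loc[:, [s for s in metadata.sample_ids if s in data.columns]]
    return FeatureTable(data, kingdom=kingdom, level="genus", mode="counts")


def simulate_performance(
    metadata: SampleMetadata,
    config: CohortConfig,
    stability_map: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Per-subject TTE seconds at each time point, linked to stability.

    Pre and post TTE vary tightly (``tte_noise`` percent SD) around a
    subject baseline drawn from the arm's (mean, SD); the mid TTE is set
    so that the percent change from the subject's realised pre value is

        arm_effect[arm] + beta * (log kappa_i - mean_arm log kappa) + eps,

    eps ~ N(0, sigma). Centring log kappa within the arm keeps the arm's
    expected mean change at its prescribed effect while making
    higher-kappa (more stable) subjects change less adversely.
    """
    if stability_map is None:
        stability_map = resolve_stability(config, metadata)
    missing = [s for s in metadata.subjects if s not in stability_map]
    if missing:
        raise ConfigError(f"stability_map missing subjects: {missing}")
    beta, sigma = config.performance_link

    log_kappa = {s: np.log(stability_map[s]) for s in metadata.subjects}
    arm_mean_logk: dict[str, float] = {}
    for arm in metadata.arms:
        arm_subjects = [s for s in metadata.subjects if metadata.arm_of(s) == arm]
        arm_mean_logk[arm] = float(np.mean([log_kappa[s] for s in arm_subjects]))

    rows = []
    for si, subj in enumerate(sorted(metadata.subjects)):
        rng = _rng(config.seed, 2, si)
        arm = metadata.arm_of(subj)
        mean, sd = config.tte_baseline.get(arm, (150.0, 30.0))
        baseline = float(np.clip(rng.normal(mean, sd), 0.3 * mean, None))
        pre = baseline * (1 + config.tte_noise / 100.0 * rng.standard_normal())
        post = baseline * (1 + config.tte_noise / 100.0 * rng.standard_normal())
        effect = config.arm_effect.get(arm, 0.0)
        change = (
            effect
            + beta * (log_kappa[subj] - arm_mean_logk[arm])
            + (sigma * rng.standard_normal() if sigma > 0 else 0.0)
        )
        mid = pre * (1 + change / 100.0)
        tte = {
            metadata.time_order[0]: pre,
            metadata.time_order[1]: mid,
            metadata.time_order[2]: post,
        }
        for tp, val in tte.items():
            rows.append(
                {"subject": subj, "arm": arm, "time_point": tp,
                 "tte_seconds": max(val, 1e-6)}
            )
    return pd.DataFrame(rows)


def simulate_vog_hits(
    n_queries: int, params: VOGHitParams | None = None, seed: int = 0
) -> pd.DataFrame:
    """Synthetic multi-target VOG alignment hit table.

    Each query receives 1..max_hits candidate target alignments with a
    classification status ("actual" or "putative"), a V.score (higher is
    better) and an E.score (lower is better). When multiple hits are
    allowed, the first query always receives at least two, so the
    disambiguation rule is always exercised.
    """
    if n_queries < 1:
        raise ConfigError(f"n_queries must be >= 1, got {n_queries}")
    params = params or VOGHitParams()
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(3,)))
    rows = []
    for q in range(n_queries):
        n_hits = int(rng.integers(1, params.max_hits_per_query + 1))
        if q == 0 and params.max_hits_per_query > 1:
            n_hits = max(n_hits, 2)
        targets = rng.choice(params.n_targets, size=n_hits, replace=False)
        for t in targets:
            status = "actual" if rng.random() < params.p_actual else "putative"
            rows.append(
                {
                    "query": f"q{q + 1:05d}",
                    "target": f"VOG{int(t) + 1:05d}",
                    "status": status,
                    "v_score": float(np.round(rng.uniform(1.0, 10.0), 3)),
                    "e_score": float(10.0 ** rng.uniform(-30.0, -2.0)),
                }
            )
    return pd.DataFrame(rows)


def simulate_study(
    config: CohortConfig,
) -> tuple[SampleMetadata, dict[str, FeatureTable], pd.DataFrame]:
    """Convenience wrapper: metadata, all kingdom tables, and performance."""
    metadata = make_cohort(config)
    tables = {
        k: simulate_feature_table(metadata, config, k) for k in KINGDOMS
    }
    perf = simulate_performance(metadata, config)
    return metadata, tables, perf
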