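import numpy as np
import pandas as pd
import pytest

from gutstab import CohortConfig, make_cohort, simulate_feature_table, simulate_performance
from gutstab.tables import DissimilarityMatrix, FeatureTable


@pytest.fixture(scope="session")
def small_config():
    """2 subjects/arm cohort kept tiny for fast unit tests."""
    return CohortConfig(
        seed=11,
        n_subjects_per_arm=2,
        n_features={"bacterial": 20, "FVP": 12, "IV": 12, "VOG-abundance": 30},
        library_size={"bacterial": 2000, "FVP": 234, "IV": 187, "VOG-abundance": 1500},
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    metadata = make_cohort(small_config)
    tables = {
        k: simulate_feature_table(metadata, small_config, k)
        for k in ("bacterial", "FVP", "IV", "VOG-abundance")
    }
    perf = simulate_performance(metadata, small_config)
    return metadata, tables, perf


@pytest.fixture(scope="session")
def study_cohort():
    """Full-size emulated study: 8 subjects per arm, three kingdoms."""
    config = CohortConfig(seed=5)
    metadata = make_cohort(config)
    tables = {
        k: simulate_feature_table(metadata, config, k)
        for k in ("bacterial", "FVP", "IV")
    }
    perf = simulate_performance(metadata, config)
    return config, metadata, tables, perf


def euclidean_dissimilarity(points: np.ndarray, ids=None) -> DissimilarityMatrix:
    """Distance matrix of a coordinate cloud — the PCoA test oracle's input."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.shape[0] == 1:
        pts = pts.T
    n = pts.shape[0]
    ids = ids or [f"s{i}" for i in range(n)]
    diff = pts[:, None, :] - pts[None, :, :]
    d = np.sqrt((diff**2).sum(axis=-1))
    return DissimilarityMatrix(pd.DataFrame(d, index=ids, columns=ids), metric="euclidean")


def table_from_array(values, kingdom="bacterial", mode="counts", prefix="f", samples=None):
    values = np.asarray(values, dtype=float)
    n_feat, n_samp = values.shape
    samples = samples or [f"s{j}" for j in range(n_samp)]
    df = pd.DataFrame(
        values, index=[f"{prefix}{i}" for i in range(n_feat)], columns=samples
    )
    return FeatureTable(df, kingdom=kingdom, mode=mode)
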