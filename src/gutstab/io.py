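"""Plain-text (TSV/JSON/YAML) readers and writers for all artifacts.

Feature tables are TSV with features as rows, samples as columns and the
feature id in the first column; metadata and performance tables are TSV
with a header row; dissimilarity matrices are square TSV with sample ids
as the first row and column. Comment lines prefixed ``#`` (used to record
the generating seed) are permitted at the top of any file and ignored on
read.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .tables import DissimilarityMatrix, FeatureTable, SampleMetadata, TableError

__all__ = [
    "read_feature_table",
    "write_feature_table",
    "read_metadata",
    "write_metadata",
    "read_performance",
    "write_performance",
    "read_dissimilarity",
    "write_dissimilarity",
    "read_vog_hits",
    "write_vog_hits",
    "read_class_mapping",
    "write_json",
    "load_config_file",
]


def _header_comments(seed: int | None, extra: Mapping[str, str] | None = None) -> str:
    lines = []
    if seed is not None:
        lines.append(f"# seed: {seed}")
    for k, v in (extra or {}).items():
        lines.append(f"# {k}: {v}")
    return "".join(line + "\n" for line in lines)


def write_feature_table(
    table: FeatureTable, path: str | Path, *, seed: int | None = None
) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(
            _header_comments(seed, {"kingdom": table.kingdom, "level": table.level,
                                    "mode": table.mode})
        )
        df = table.data.copy()
        df.index.name = "feature_id"
        df.to_csv(fh, sep="\t")


def read_feature_table(
    path: str | Path, *, kingdom: str = "bacterial", level: str = "genus",
    mode: str = "counts",
) -> FeatureTable:
    path = Path(path)
    meta = _read_hash_metadata(path)
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                header = line.rstrip("\n").split("\t")[1:]
                break
        else:
            raise TableError(f"{path}: empty file")
    dup = {c for c in header if header.count(c) > 1}
    if dup:
        raise TableError(f"{path}: duplicated sample columns {sorted(dup)}")
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0, float_precision="round_trip")
    df.index = df.index.astype(str)
    if df.isna().any().any():
        raise TableError(f"{path}: ragged or missing entries")
    neg = df.lt(0).any(axis=1)
    if neg.any():
        raise TableError(f"{path}: negative counts in rows {df.index[neg].tolist()}")
    # integer counts stay integer through a round trip
    values = df.to_numpy()
    if np.issubdtype(values.dtype, np.floating) and np.all(values == np.round(values)):
        df = df.astype(np.int64) if mode == "counts" else df
    return FeatureTable(
        df,
        kingdom=meta.get("kingdom", kingdom),
        level=meta.get("level", level),
        mode=meta.get("mode", mode),
    )


def _read_hash_metadata(path: Path) -> dict[str, str]:
    out = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line[1:].strip()
            if ":" in body:
                k, v = body.split(":", 1)
                out[k.strip()] = v.strip()
    return out


def write_metadata(
    metadata: SampleMetadata, path: str | Path, *, seed: int | None = None
) -> None:
    with open(path, "w") as fh:
        fh.write(_header_comments(seed, {"time_order": ",".join(metadata.time_order)}))
        df = metadata.frame.copy()
        df.index.name = "sample"
        df.to_csv(fh, sep="\t")


def read_metadata(path: str | Path) -> SampleMetadata:
    path = Path(path)
    meta = _read_hash_metadata(path)
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0, float_precision="round_trip")
    time_order = tuple(meta.get("time_order", "pre,mid,post").split(","))
    return SampleMetadata(df, time_order=time_order)


def write_performance(
    perf: pd.DataFrame, path: str | Path, *, seed: int | None = None
) -> None:
    with open(path, "w") as fh:
        fh.write(_header_comments(seed))
        # %.17g guarantees an exact float round trip through the text file
        perf.to_csv(fh, sep="\t", index=False, float_format="%.17g")


def read_performance(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", float_precision="round_trip")
    required = {"subject", "arm", "time_point", "tte_seconds"}
    missing = required - set(df.columns)
    if missing:
        raise TableError(f"{path}: performance table missing columns {sorted(missing)}")
    return df


def write_dissimilarity(
    D: DissimilarityMatrix, path: str | Path, *, seed: int | None = None
) -> None:
    with open(path, "w") as fh:
        fh.write(_header_comments(seed, {"metric": D.metric}))
        D.data.to_csv(fh, sep="\t", float_format="%.17g")


def read_dissimilarity(path: str | Path) -> DissimilarityMatrix:
    path = Path(path)
    meta = _read_hash_metadata(path)
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0, float_precision="round_trip")
    df.columns = df.columns.astype(str)
    df.index = df.index.astype(str)
    return DissimilarityMatrix(df, metric=meta.get("metric", "unknown"))


def write_vog_hits(hits: pd.DataFrame, path: str | Path, *, seed: int | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(_header_comments(seed))
        hits.to_csv(fh, sep="\t", index=False)


def read_vog_hits(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", float_precision="round_trip")
    required = {"query", "target", "status", "v_score", "e_score"}
    missing = required - set(df.columns)
    if missing:
        raise TableError(f"{path}: hit table missing columns {sorted(missing)}")
    return df


def read_class_mapping(path: str | Path) -> dict[str, str]:
    """Two-column TSV: VOG id, class label."""
    df = pd.read_csv(path, sep="\t", comment="#", header=None, names=["vog", "class"])
    return dict(zip(df["vog"].astype(str), df["class"].astype(str)))


def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def load_config_file(path: str | Path) -> dict:
    """Load a YAML or JSON run configuration document."""
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        return yaml.safe_load(text)
    if path.suffix == ".json":
        return json.loads(text)
    # fall back: YAML is a superset of JSON
    return yaml.safe_load(text)
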