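"""Tabular I/O: TSV feature tables, metadata, qPCR plates, configs.

Feature-table TSV dialect: tab-separated, first column the SV id, last
column ``taxonomy`` (semicolon-delimited 7-rank lineage), every other
column a sample of integer counts.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .containers import FeatureTable, make_metadata

__all__ = [
    "read_feature_table", "write_feature_table",
    "read_metadata", "write_metadata",
    "read_qpcr_wells", "write_qpcr_wells",
    "read_standards", "write_standards",
    "write_truth", "read_truth",
    "load_config", "dump_config",
    "write_json",
]


def write_feature_table(table: FeatureTable, path) -> None:
    out = table.counts.copy()
    out["taxonomy"] = table.taxonomy
    out.index.name = out.index.name or "sv_id"
    out.to_csv(path, sep="\t")


def read_feature_table(path) -> FeatureTable:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype={0: str})
    if "taxonomy" not in df.columns:
        raise ValueError(f"{path}: missing 'taxonomy' column (must be last)")
    if df.columns[-1] != "taxonomy":
        raise ValueError(f"{path}: 'taxonomy' must be the last column")
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique()
        raise ValueError(f"{path}: duplicate SV id(s): {list(dupes)[:5]}")
    taxonomy = df.pop("taxonomy").fillna("")
    counts = df
    arr = counts.to_numpy()
    try:
        as_int = counts.astype(np.int64)
    except (ValueError, TypeError) as exc:
        raise ValueError(f"{path}: non-integer counts") from exc
    if not np.array_equal(as_int.to_numpy(dtype=float), arr.astype(float)):
        raise ValueError(f"{path}: non-integer counts")
    return FeatureTable(as_int, taxonomy)


def write_metadata(metadata: pd.DataFrame, path) -> None:
    out = metadata.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t")


def read_metadata(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    if "sample_id" not in df.columns:
        raise ValueError(f"{path}: missing 'sample_id' column")
    return make_metadata(df)


def write_qpcr_wells(wells: pd.DataFrame, path) -> None:
    out = wells.copy()
    out["ct"] = out["ct"].map(
        lambda v: "Undetermined" if pd.isna(v) else f"{v:.4f}")
    out.to_csv(path, sep="\t", index=False)


def read_qpcr_wells(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    for col in ("sample_id", "ct"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing '{col}' column")
    df["ct"] = pd.to_numeric(df["ct"], errors="coerce")
    return df


def write_standards(standards: pd.DataFrame, path) -> None:
    out = standards.copy()
    out["ct"] = out["ct"].map(
        lambda v: "Undetermined" if pd.isna(v) else f"{v:.4f}")
    out.to_csv(path, sep="\t", index=False)


def read_standards(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if "copies_per_reaction" not in df.columns or "ct" not in df.columns:
        raise ValueError(f"{path}: standards need copies_per_reaction and ct columns")
    df["ct"] = pd.to_numeric(df["ct"], errors="coerce")
    return df


def write_truth(truth: dict, path) -> None:
    Path(path).write_text(json.dumps(truth, indent=1))


def read_truth(path) -> dict:
    return json.loads(Path(path).read_text())


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return cfg or {}


def dump_config(cfg: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return v if np.isfinite(v) else None
    if isinstance(obj, np.ndarray):
        return _jsonable(obj.tolist())
    if isinstance(obj, pd.DataFrame):
        return _jsonable(obj.reset_index().to_dict(orient="records"))
    if isinstance(obj, pd.Series):
        return _jsonable(obj.to_dict())
    return obj


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(_jsonable(obj), indent=1))
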