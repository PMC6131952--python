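"""Core in-memory containers: feature tables and sample metadata.

A feature table is a sequence-variant (SV) x sample matrix of read counts
with a 7-rank taxonomic lineage attached to every SV.  Sample metadata is a
pandas DataFrame indexed by sample id with the columns ``run_id``,
``sample_type`` ({mock, stool, negative}), ``specimen_id`` (nullable) and
``dilution_factor`` (nullable, >= 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SAMPLE_TYPES = ("mock", "stool", "negative")

#: Canonical rank names for semicolon-delimited 7-rank lineages.
RANKS = ("kingdom", "phylum", "class", "order", "family", "genus", "species")

RANK_PREFIXES = ("k__", "p__", "c__", "o__", "f__", "g__", "s__")


@dataclass
class FeatureTable:
    """SV x sample abundance matrix with per-SV taxonomy.

    ``counts`` rows are SVs, columns are samples.  Raw tables hold
    nonnegative integers; derived tables (e.g. relative abundances) hold
    nonnegative floats.  ``taxonomy`` is a Series of semicolon-delimited
    lineages aligned to ``counts.index``.
    """

    counts: pd.DataFrame
    taxonomy: pd.Series = field(default=None)

    def __post_init__(self) -> None:
        if not isinstance(self.counts, pd.DataFrame):
            self.counts = pd.DataFrame(self.counts)
        if self.counts.index.has_duplicates:
            dupes = self.counts.index[self.counts.index.duplicated()].unique()
            raise ValueError(f"duplicate SV ids: {list(dupes)[:5]}")
        if self.counts.columns.has_duplicates:
            dupes = self.counts.columns[self.counts.columns.duplicated()].unique()
            raise ValueError(f"duplicate sample ids: {list(dupes)[:5]}")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("feature table contains negative entries")
        if self.taxonomy is None:
            self.taxonomy = pd.Series("", index=self.counts.index, dtype=object)
        else:
            self.taxonomy = pd.Series(self.taxonomy)
            if not self.taxonomy.index.equals(self.counts.index):
                try:
                    self.taxonomy = self.taxonomy.reindex(self.counts.index)
                except Exception as exc:  # pragma: no cover - defensive
                    raise ValueError("taxonomy index does not match SV ids") from exc
                if self.taxonomy.isna().any():
                    missing = self.taxonomy.index[self.taxonomy.isna()]
                    raise ValueError(f"taxonomy missing for SVs: {list(missing)[:5]}")

    # -- convenience -----------------------------------------------------
    @property
    def sv_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    @property
    def n_svs(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def sample_totals(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def total_reads(self) -> float:
        return float(self.counts.to_numpy().sum())

    def select_svs(self, sv_ids) -> "FeatureTable":
        return FeatureTable(self.counts.loc[sv_ids], self.taxonomy.loc[sv_ids])

    def select_samples(self, sample_ids) -> "FeatureTable":
        return FeatureTable(self.counts[list(sample_ids)], self.taxonomy)

    def copy(self) -> "FeatureTable":
        return FeatureTable(self.counts.copy(), self.taxonomy.copy())

    def __eq__(self, other) -> bool:
        if not isinstance(other, FeatureTable):
            return NotImplemented
        return self.counts.equals(other.counts) and self.taxonomy.equals(other.taxonomy)


def make_metadata(frame: pd.DataFrame) -> pd.DataFrame:
    """Validate and normalise a sample-metadata frame.

    Accepts a frame indexed by sample id (or with a ``sample_id`` column)
    and enforces the closed sample-type vocabulary and dilution-factor
    bounds.  Returns a normalised copy.
    """
    md = frame.copy()
    if "sample_id" in md.columns:
        md = md.set_index("sample_id")
    if md.index.has_duplicates:
        raise ValueError("duplicate sample ids in metadata")
    for col in ("run_id", "sample_type"):
        if col not in md.columns:
            raise ValueError(f"metadata missing required column '{col}'")
    bad = set(md["sample_type"]) - set(SAMPLE_TYPES)
    if bad:
        raise ValueError(f"unknown sample_type values: {sorted(bad)}")
    if "specimen_id" not in md.columns:
        md["specimen_id"] = pd.NA
    if "dilution_factor" not in md.columns:
        md["dilution_factor"] = np.nan
    md["dilution_factor"] = pd.to_numeric(md["dilution_factor"], errors="coerce")
    df = md["dilution_factor"]
    if (df.dropna() < 1).any():
        raise ValueError("dilution_factor values must be >= 1")
    return md


def check_sample_consistency(table: FeatureTable, metadata: pd.DataFrame) -> None:
    """Every sample in the table must have metadata."""
    missing = table.sample_ids.difference(metadata.index)
    if len(missing):
        raise ValueError(f"samples without metadata: {list(missing)[:5]}")


def split_lineage(lineage: str) -> list[str]:
    """Split a semicolon-delimited lineage into per-rank names.

    Rank prefixes (``k__`` ...) are stripped; missing or empty ranks come
    back as empty strings.  Always returns exactly 7 entries.
    """
    parts = [p.strip() for p in str(lineage).split(";")]
    names = []
    for i in range(len(RANKS)):
        name = parts[i] if i < len(parts) else ""
        for pref in RANK_PREFIXES:
            if name.startswith(pref):
                name = name[len(pref):]
                break
        names.append(name.strip())
    return names


def join_lineage(names) -> str:
    """Inverse of :func:`split_lineage` using canonical prefixes."""
    return "; ".join(f"{RANK_PREFIXES[i]}{names[i] if i < len(names) else ''}"
                     for i in range(len(RANKS)))
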