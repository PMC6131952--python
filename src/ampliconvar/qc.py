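"""Negative-control-based quality control for amplicon feature tables.

The pipeline order is fixed: contaminant scoring -> contaminant removal ->
read-depth threshold selection -> sample filtering -> rarefaction (alpha
diversity) or relative-abundance transform (everything else).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .containers import (FeatureTable, RANKS, check_sample_consistency,
                         split_lineage)

__all__ = [
    "contaminant_scores",
    "remove_contaminants",
    "select_depth_threshold",
    "filter_samples_by_depth",
    "rarefy",
    "relative_abundance",
    "collapse_rank",
    "qc_pipeline",
]


def contaminant_scores(table: FeatureTable, metadata: pd.DataFrame) -> pd.DataFrame:
    """Per-SV contaminant score.

    ``score = (reads of the SV in negative controls) / (reads of the SV in
    all samples)``: 0 for SVs never seen in a negative control, 1 for SVs
    seen only there.  Intermediate values estimate how likely the SV is to
    be reagent-derived.  SVs with zero total count score 0 and are flagged.
    """
    check_sample_consistency(table, metadata)
    neg_ids = metadata.index[metadata["sample_type"] == "negative"]
    neg_ids = table.sample_ids.intersection(neg_ids)
    total = table.counts.sum(axis=1).astype(float)
    neg = table.counts[list(neg_ids)].sum(axis=1).astype(float) if len(neg_ids) \
        else pd.Series(0.0, index=table.sv_ids)
    if not len(neg_ids):
        warnings.warn("no negative-control samples: all contaminant scores are 0",
                      stacklevel=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        score = np.where(total > 0, neg / total.replace(0, np.nan), 0.0)
    out = pd.DataFrame({
        "score": score,
        "negative_count": neg,
        "total_count": total,
        "zero_total": total == 0,
    }, index=table.sv_ids)
    out["score"] = out["score"].fillna(0.0)
    return out


def remove_contaminants(table: FeatureTable, scores: pd.DataFrame,
                        threshold: float = 0.1) -> FeatureTable:
    """Drop SVs whose score strictly exceeds ``threshold``.

    Reading "exceeded" literally: an SV exactly at the threshold is kept.
    Zero-total bookkeeping SVs are dropped silently.  Samples and retained
    counts are untouched.
    """
    if not 0 <= threshold <= 1:
        raise ValueError("threshold must be in [0, 1]")
    s = scores["score"].reindex(table.sv_ids)
    keep = (s <= threshold) & ~scores["zero_total"].reindex(table.sv_ids).fillna(False)
    return table.select_svs(table.sv_ids[keep.to_numpy(dtype=bool)])


def select_depth_threshold(depths: pd.Series, metadata: pd.DataFrame,
                           max_negatives_retained: int = 2,
                           manual_override: int | None = None) -> int:
    """Choose a read-depth cutoff from the post-filter depth distribution.

    Returns the smallest per-sample total of any non-negative sample such
    that at most ``max_negatives_retained`` negative controls sit at or
    above it.  This operationalises picking the inflection point of the
    read-count distribution by its consequence: almost no negatives
    survive.  ``manual_override`` wins when given.
    """
    if manual_override is not None:
        if manual_override < 1:
            raise ValueError("depth threshold must be >= 1")
        return int(manual_override)
    is_neg = metadata.loc[depths.index, "sample_type"] == "negative"
    sample_depths = np.sort(depths[~is_neg].to_numpy())
    neg_depths = np.sort(depths[is_neg].to_numpy())
    if sample_depths.size == 0:
        raise ValueError("no non-negative samples to set a depth threshold from")
    for d in sample_depths:
        n_retained = int((neg_depths >= d).sum())
        if n_retained <= max_negatives_retained:
            return int(d)
    achievable = int((neg_depths >= sample_depths[-1]).sum())
    raise ValueError(
        "no non-negative sample depth retains <= "
        f"{max_negatives_retained} negatives (minimum achievable: {achievable})")


def filter_samples_by_depth(table: FeatureTable, metadata: pd.DataFrame,
                            threshold: int):
    """Keep samples with at least ``threshold`` reads.

    Returns (table, metadata, report); the report counts retained and
    dropped samples per sample type.
    """
    if threshold < 1:
        raise ValueError("threshold must be >= 1")
    check_sample_consistency(table, metadata)
    totals = table.sample_totals()
    keep = totals.index[totals >= threshold]
    if not len(keep):
        raise ValueError(f"depth threshold {threshold} drops every sample")
    md = metadata.loc[metadata.index.intersection(table.sample_ids)]
    report = {"threshold": int(threshold), "retained": {}, "dropped": {}}
    for stype in ("mock", "stool", "negative"):
        ids = md.index[md["sample_type"] == stype]
        n_keep = int(len(ids.intersection(keep)))
        report["retained"][stype] = n_keep
        report["dropped"][stype] = int(len(ids) - n_keep)
    return table.select_samples(keep), metadata.loc[keep], report


def rarefy(table: FeatureTable, depth: int,
           rng: np.random.Generator | int | None = 0) -> FeatureTable:
    """Subsample every sample to ``depth`` reads without replacement.

    Multivariate hypergeometric draws; samples whose total is below the
    depth are dropped (not an error).
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    totals = table.sample_totals()
    keep = [s for s in table.sample_ids if totals[s] >= depth]
    out = {}
    for s in keep:
        col = table.counts[s].to_numpy(dtype=np.int64)
        if col.sum() == depth:
            out[s] = col
        else:
            out[s] = rng.multivariate_hypergeometric(col, depth)
    frame = pd.DataFrame(out, index=table.sv_ids, dtype=np.int64)
    return FeatureTable(frame, table.taxonomy)


def relative_abundance(table: FeatureTable) -> FeatureTable:
    """Divide each sample by its total so columns sum to 1."""
    totals = table.sample_totals()
    zero = totals.index[totals == 0]
    if len(zero):
        raise ValueError(f"zero-total samples: {list(zero)[:5]}")
    return FeatureTable(table.counts / totals, table.taxonomy)


def _rank_keys(taxonomy: pd.Series, rank: str) -> pd.Series:
    depth = RANKS.index(rank) + 1
    keys = {}
    for sv, lineage in taxonomy.items():
        names = split_lineage(lineage)
        if names[depth - 1]:
            keys[sv] = "; ".join(names[:depth])
        else:
            parent = ""
            for name in names[:depth - 1]:
                if name:
                    parent = name
                else:
                    break
            keys[sv] = f"unclassified_{parent}" if parent else "unclassified_"
    return pd.Series(keys)


def collapse_rank(table: FeatureTable, rank: str = "genus") -> FeatureTable:
    """Sum SVs sharing their lineage prefix down to ``rank``.

    ``rank='sv'`` is the identity.  SVs unassigned at the rank are pooled
    under ``unclassified_<deepest assigned parent>`` so reads are conserved.
    """
    if rank == "sv":
        return table.copy()
    if rank not in RANKS:
        raise ValueError(f"rank must be 'sv' or one of {RANKS}")
    keys = _rank_keys(table.taxonomy, rank)
    grouped = table.counts.groupby(keys.loc[table.sv_ids].to_numpy()).sum()
    grouped.index.name = rank
    # representative lineage: truncate the first member's lineage
    depth = RANKS.index(rank) + 1
    tax = {}
    for key, svs in table.sv_ids.to_series().groupby(keys.loc[table.sv_ids].to_numpy()):
        names = split_lineage(table.taxonomy[svs.iloc[0]])[:depth]
        tax[key] = "; ".join(names)
    return FeatureTable(grouped, pd.Series(tax).loc[grouped.index])


def qc_pipeline(table: FeatureTable, metadata: pd.DataFrame,
                contaminant_threshold: float = 0.1,
                max_negatives_retained: int = 2,
                depth_override: int | None = None,
                rarefaction_seed: int = 0) -> dict:
    """Run the fixed QC sequence and record per-stage accounting.

    Returns a dict with the filtered table, its metadata, the rarefied
    table, relative abundances, the contaminant score table, the chosen
    depth threshold, and a stage-by-stage report.
    """
    check_sample_consistency(table, metadata)
    report = {"input": {"n_svs": table.n_svs, "n_samples": table.n_samples,
                        "n_reads": table.total_reads()}}
    scores = contaminant_scores(table, metadata)
    filtered = remove_contaminants(table, scores, contaminant_threshold)
    report["contaminant_filter"] = {
        "threshold": contaminant_threshold,
        "n_svs_removed": int(table.n_svs - filtered.n_svs),
        "n_svs_retained": filtered.n_svs,
        "reads_removed": table.total_reads() - filtered.total_reads(),
    }
    depth = select_depth_threshold(filtered.sample_totals(), metadata,
                                   max_negatives_retained, depth_override)
    kept, kept_md, depth_report = filter_samples_by_depth(filtered, metadata, depth)
    report["depth_filter"] = depth_report
    rare = rarefy(kept, depth, np.random.default_rng(rarefaction_seed))
    relab = relative_abundance(kept)
    report["output"] = {"n_svs": kept.n_svs, "n_samples": kept.n_samples,
                        "rarefaction_depth": int(depth)}
    return {"table": kept, "metadata": kept_md, "rarefied": rare,
            "relabund": relab, "scores": scores, "depth_threshold": int(depth),
            "report": report}
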