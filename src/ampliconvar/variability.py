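"""Reproducibility metrics: CV tables, one-way ICC, Levey-Jennings flags,
Shannon diversity, and the CV-abundance association.

Intra-assay variation is variation within one sequencing run; inter-assay
variation pools the same material across runs.  The coefficient of
variation is reported in percent (100 * SD / mean, SD with the n-1
denominator); a taxon never detected in a stratum has an undefined CV,
carried as NaN and never coerced to 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import FeatureTable
from .qc import collapse_rank

__all__ = [
    "cv_table",
    "mean_intra_cv",
    "ICCResult",
    "icc_oneway_values",
    "icc_by_taxon",
    "levey_jennings",
    "shannon",
    "cv_abundance_association",
]


def _select_samples(metadata: pd.DataFrame, sample_types, max_dilution):
    md = metadata
    mask = md["sample_type"].isin(sample_types)
    if max_dilution is not None:
        df = md["dilution_factor"]
        mask &= df.isna() | (df <= max_dilution)
    return md.index[mask]


def cv_table(relabund: FeatureTable, metadata: pd.DataFrame,
             stratify_by: str = "run", rank: str = "genus",
             sample_types=("mock",), max_dilution: float | None = 1.0) -> pd.DataFrame:
    """Per-taxon mean relative abundance and CV within each stratum.

    ``stratify_by='run'`` gives intra-assay strata, ``'none'`` pools all
    selected samples (inter-assay), ``'dilution'`` stratifies by dilution
    factor.  Negative controls are always excluded; by default only
    undiluted mock samples enter.  Strata with fewer than two samples are
    skipped with a warning.
    """
    ids = _select_samples(metadata, sample_types, max_dilution)
    ids = relabund.sample_ids.intersection(ids)
    collapsed = collapse_rank(relabund.select_samples(ids), rank)
    md = metadata.loc[ids]
    if stratify_by == "run":
        strata = md.groupby("run_id").groups
    elif stratify_by == "none":
        strata = {"all": ids}
    elif stratify_by == "dilution":
        strata = md.groupby("dilution_factor").groups
    else:
        raise ValueError("stratify_by must be 'run', 'none' or 'dilution'")

    rows = []
    for stratum, sids in sorted(strata.items(), key=lambda kv: str(kv[0])):
        sids = collapsed.sample_ids.intersection(sids)
        if len(sids) < 2:
            warnings.warn(f"stratum {stratum!r} has < 2 samples; skipped",
                          stacklevel=2)
            continue
        block = collapsed.counts[list(sids)]
        mean = block.mean(axis=1)
        sd = block.std(axis=1, ddof=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            cv = 100.0 * sd / mean
        cv[mean == 0] = np.nan
        for taxon in block.index:
            rows.append(dict(taxon=taxon, stratum=stratum,
                             mean_ra=float(mean[taxon]), sd_ra=float(sd[taxon]),
                             cv_pct=float(cv[taxon]) if np.isfinite(cv[taxon]) else np.nan,
                             n_samples=int(len(sids)),
                             n_detected=int((block.loc[taxon] > 0).sum())))
    return pd.DataFrame(rows, columns=["taxon", "stratum", "mean_ra", "sd_ra",
                                       "cv_pct", "n_samples", "n_detected"])


def mean_intra_cv(cvtab: pd.DataFrame) -> pd.DataFrame:
    """Unweighted mean (and range) of per-stratum CVs for each taxon.

    Strata where the taxon was not detected (undefined CV) are dropped
    from the mean, mirroring "not detected" entries in run-level reports.
    """
    rows = []
    for taxon, grp in cvtab.groupby("taxon"):
        defined = grp["cv_pct"].dropna()
        rows.append(dict(taxon=taxon,
                         mean_cv=float(defined.mean()) if len(defined) else np.nan,
                         min_cv=float(defined.min()) if len(defined) else np.nan,
                         max_cv=float(defined.max()) if len(defined) else np.nan,
                         n_strata=int(len(grp)), n_defined=int(len(defined)),
                         mean_ra=float(grp["mean_ra"].mean())))
    return pd.DataFrame(rows).set_index("taxon")


@dataclass(frozen=True)
class ICCResult:
    """One-way random-effects, single-measure ICC from ANOVA mean squares."""

    icc: float
    ms_between: float
    ms_within: float
    n_groups: int
    mean_group_size: float  # n0 for unbalanced designs
    n_obs: int


def icc_oneway_values(values, groups) -> ICCResult:
    """ICC(1,1) for a single variable grouped by ``groups``.

    ``ICC = (MSB - MSW) / (MSB + (n0 - 1) MSW)`` with the unbalanced
    effective group size ``n0 = (N - sum n_j^2 / N) / (J - 1)``.
    Singleton groups are allowed (they contribute between-group df only).
    Identical values everywhere leave the ICC undefined (NaN).
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if values.shape != groups.shape:
        raise ValueError("values and groups must align")
    labels, codes = np.unique(groups, return_inverse=True)
    J, N = len(labels), len(values)
    if J < 2:
        raise ValueError("need at least 2 groups")
    n_j = np.bincount(codes).astype(float)
    grand = values.mean()
    group_means = np.bincount(codes, weights=values) / n_j
    ssb = float(np.sum(n_j * (group_means - grand) ** 2))
    ssw = float(np.sum((values - group_means[codes]) ** 2))
    df_b, df_w = J - 1, N - J
    if df_w < 1:
        raise ValueError("need residual degrees of freedom (some group with > 1 sample)")
    msb, msw = ssb / df_b, ssw / df_w
    n0 = (N - np.sum(n_j ** 2) / N) / (J - 1)
    denom = msb + (n0 - 1.0) * msw
    icc = np.nan if denom == 0 else (msb - msw) / denom
    return ICCResult(icc=float(icc), ms_between=msb, ms_within=msw,
                     n_groups=J, mean_group_size=float(n0), n_obs=N)


def icc_by_taxon(relabund: FeatureTable, metadata: pd.DataFrame,
                 group_by: str = "run_id", rank: str = "genus",
                 sample_types=("mock",), max_dilution: float | None = 1.0):
    """Per-taxon one-way ICC with run (or other factor) as the grouping.

    Returns ``(per_taxon Series, summary float)`` where the summary is the
    unweighted mean of defined per-taxon ICCs at the requested rank.
    """
    ids = _select_samples(metadata, sample_types, max_dilution)
    ids = relabund.sample_ids.intersection(ids)
    collapsed = collapse_rank(relabund.select_samples(ids), rank)
    groups = metadata.loc[list(collapsed.sample_ids), group_by].to_numpy()
    per_taxon = {}
    for taxon in collapsed.sv_ids:
        vals = collapsed.counts.loc[taxon].to_numpy(dtype=float)
        if np.allclose(vals, vals[0]):
            per_taxon[taxon] = np.nan
            continue
        per_taxon[taxon] = icc_oneway_values(vals, groups).icc
    series = pd.Series(per_taxon, name="icc")
    defined = series.dropna()
    return series, (float(defined.mean()) if len(defined) else np.nan)


def levey_jennings(relabund: FeatureTable, metadata: pd.DataFrame,
                   rank: str = "genus", k_sd: float = 2.0,
                   sample_types=("mock",), max_dilution: float | None = 1.0):
    """Control-chart flags: observations beyond ``k_sd`` SDs of the mean.

    Mean and SD are computed per taxon over all selected samples; a zero
    SD yields no flags.  Returns ``(stats, flags)`` where ``flags`` is a
    long frame with one row per (taxon, sample) and a boolean ``flagged``.
    """
    ids = _select_samples(metadata, sample_types, max_dilution)
    ids = relabund.sample_ids.intersection(ids)
    if len(ids) < 3:
        raise ValueError("need at least 3 samples for a control chart")
    collapsed = collapse_rank(relabund.select_samples(ids), rank)
    block = collapsed.counts
    mean = block.mean(axis=1)
    sd = block.std(axis=1, ddof=1)
    stats_df = pd.DataFrame({"mean": mean, "sd": sd})
    run_order = metadata.loc[list(block.columns), "run_id"]
    order = run_order.sort_values(kind="stable").index
    rows = []
    for taxon in block.index:
        m, s = mean[taxon], sd[taxon]
        for sample in order:
            x = block.at[taxon, sample]
            flagged = bool(s > 0 and abs(x - m) > k_sd * s)
            rows.append(dict(taxon=taxon, sample_id=sample,
                             run_id=run_order[sample], value=float(x),
                             flagged=flagged))
    return stats_df, pd.DataFrame(rows)


def shannon(rarefied: FeatureTable, base: float | None = None) -> pd.Series:
    """Per-sample Shannon diversity H = -sum p log p (natural log default)."""
    totals = rarefied.sample_totals()
    zero = totals.index[totals == 0]
    if len(zero):
        raise ValueError(f"zero-total samples: {list(zero)[:5]}")
    out = {}
    log = np.log if base is None else (lambda x: np.log(x) / np.log(base))
    for s in rarefied.sample_ids:
        p = rarefied.counts[s].to_numpy(dtype=float)
        p = p[p > 0] / p.sum()
        out[s] = float(-(p * log(p)).sum())
    return pd.Series(out, name="shannon")


def cv_abundance_association(vtable: pd.DataFrame):
    """Spearman correlation between per-taxon mean abundance and CV.

    Accepts either a stratified CV table (averaged per taxon first) or the
    output of :func:`mean_intra_cv`.  Returns ``(rho, p)``; constant CVs
    give ``(nan, nan)``.
    """
    if "mean_cv" in vtable.columns:
        df = vtable[["mean_ra", "mean_cv"]].rename(columns={"mean_cv": "cv"})
    else:
        df = (vtable.groupby("taxon")
              .agg(mean_ra=("mean_ra", "mean"), cv=("cv_pct", "mean")))
    df = df.dropna()
    if len(df) < 3:
        raise ValueError("need at least 3 taxa with defined CV")
    if df["cv"].nunique() == 1 or df["mean_ra"].nunique() == 1:
        return float("nan"), float("nan")
    rho, p = stats.spearmanr(df["mean_ra"], df["cv"])
    return float(rho), float(p)
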