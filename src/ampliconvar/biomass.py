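"""qPCR quantification, dilution-series calibration, and the log-log
variance prediction model.

Absolute biomass is proxied by 16S rRNA gene copies per microliter,
quantified against a plasmid standard curve (Ct linear in log10 copies).
The variance model regresses log10(CV) on log10(copies/uL) and
log10(mean relative abundance); relative abundance enters in percent by
default, and the unit convention is stored on the fitted model so fit and
prediction can never disagree.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import linregress

from .containers import FeatureTable
from .variability import cv_table

__all__ = [
    "StandardCurve",
    "fit_standard_curve",
    "ct_from_copies",
    "quantify",
    "expected_copies",
    "build_cv_dataset",
    "VariationModel",
    "fit_variation_model",
    "predict_variation",
    "prediction_grid",
    "DEFAULT_GRID_COPIES",
    "DEFAULT_GRID_RA_PERCENT",
]

DEFAULT_TEMPLATE_VOLUME_UL = 5.0
DEFAULT_GRID_COPIES = (10.0, 1.0e3, 1.0e5)
DEFAULT_GRID_RA_PERCENT = (1.0, 5.0, 10.0, 25.0, 50.0)


@dataclass(frozen=True)
class StandardCurve:
    """Least-squares Ct ~ log10(copies/reaction) calibration.

    ``efficiency = 10**(-1/slope) - 1``; a perfectly efficient assay has
    slope -1/log10(2) ~ -3.32 and efficiency 1.0 (100 %).
    """

    slope: float
    intercept: float
    r_squared: float
    efficiency: float
    standards: tuple[float, ...]


def fit_standard_curve(standards: pd.DataFrame | list) -> StandardCurve:
    """Fit the standard curve from (copies/reaction, Ct) wells.

    Zero-copy wells are excluded from the fit (log undefined) and serve
    only as no-template checks; at least three distinct nonzero standards
    are required and the slope must be negative.
    """
    if isinstance(standards, pd.DataFrame):
        df = standards[["copies_per_reaction", "ct"]].copy()
    else:
        df = pd.DataFrame(standards, columns=["copies_per_reaction", "ct"])
    df = df[(df["copies_per_reaction"] > 0) & df["ct"].notna()]
    if df["copies_per_reaction"].nunique() < 3:
        raise ValueError("need at least 3 distinct nonzero standards")
    x = np.log10(df["copies_per_reaction"].to_numpy(dtype=float))
    y = df["ct"].to_numpy(dtype=float)
    fit = linregress(x, y)
    if fit.slope >= 0:
        raise ValueError(f"invalid standard curve: slope {fit.slope:.4g} is not negative")
    return StandardCurve(slope=float(fit.slope), intercept=float(fit.intercept),
                         r_squared=float(fit.rvalue ** 2),
                         efficiency=float(10.0 ** (-1.0 / fit.slope) - 1.0),
                         standards=tuple(sorted(df["copies_per_reaction"].unique())))


def ct_from_copies(curve: StandardCurve, copies_per_reaction: float) -> float:
    """Noise-free Ct implied by the curve (for simulation and round trips)."""
    if copies_per_reaction <= 0:
        raise ValueError("copies must be positive")
    return curve.intercept + curve.slope * math.log10(copies_per_reaction)


def quantify(ct_wells: pd.DataFrame, curve: StandardCurve,
             template_volume_ul: float = DEFAULT_TEMPLATE_VOLUME_UL) -> pd.DataFrame:
    """Invert the standard curve per sample.

    ``ct_wells`` is long-form (sample_id, well, ct); undetermined wells
    (NaN or the literal text "Undetermined") are dropped, replicate wells
    are averaged arithmetically, and an all-undetermined sample gets 0
    copies with a flag.  ``copies_per_ul = copies_per_reaction / volume``.
    """
    df = ct_wells.copy()
    df["ct"] = pd.to_numeric(df["ct"], errors="coerce")
    rows = []
    for sid, grp in df.groupby("sample_id", sort=False):
        cts = grp["ct"].dropna()
        if len(cts) == 0:
            rows.append(dict(sample_id=sid, mean_ct=np.nan, copies_per_reaction=0.0,
                             copies_per_ul=0.0, undetermined=True))
            continue
        mean_ct = float(cts.mean())
        copies_rxn = 10.0 ** ((mean_ct - curve.intercept) / curve.slope)
        rows.append(dict(sample_id=sid, mean_ct=mean_ct,
                         copies_per_reaction=float(copies_rxn),
                         copies_per_ul=float(copies_rxn / template_volume_ul),
                         undetermined=False))
    return pd.DataFrame(rows).set_index("sample_id")


def expected_copies(factors, measured_per_level) -> pd.DataFrame:
    """Naive and sequentially recalibrated expected copies per level.

    ``factors`` must be ascending with the stock (factor 1) present.
    Naive expectation divides the measured stock by the factor; the
    sequential expectation propagates each measured parent through the
    next pipetting step, ``expected_k = measured_{k-1} * f_{k-1} / f_k``,
    which absorbs any systematic per-step over-dilution.
    """
    factors = [float(f) for f in factors]
    if factors != sorted(factors) or len(set(factors)) != len(factors):
        raise ValueError("factors must be strictly ascending")
    if factors[0] != 1.0:
        raise ValueError("the stock (factor 1) must be present")
    measured = dict(zip(factors, [float(m) if m is not None and np.isfinite(m)
                                  else np.nan for m in measured_per_level]))
    stock = measured[1.0]
    rows = []
    for k, f in enumerate(factors):
        naive = stock / f
        if k == 0:
            seq = stock
        else:
            parent = measured[factors[k - 1]]
            seq = parent * factors[k - 1] / f if np.isfinite(parent) else np.nan
        rows.append(dict(dilution_factor=f, naive_expected=naive,
                         sequential_expected=seq, measured=measured[f]))
    return pd.DataFrame(rows).set_index("dilution_factor")


def build_cv_dataset(relabund: FeatureTable, metadata: pd.DataFrame,
                     qpcr: pd.DataFrame, rank: str = "genus",
                     min_mean_ra: float = 0.001,
                     min_detected: int = 3) -> pd.DataFrame:
    """Assemble the taxon x dilution-level CV regression dataset.

    Per taxon and level: CV and mean relative abundance across the level's
    replicates, with the level's biomass taken as the mean measured
    copies/uL of its replicates.  Rows are dropped when the mean abundance
    falls below ``min_mean_ra`` (fraction), the taxon is detected in fewer
    than ``min_detected`` replicates, or the CV is undefined or zero (its
    log would be undefined) -- the quantities entering the model must all
    be strictly positive.
    """
    cvtab = cv_table(relabund, metadata, stratify_by="dilution", rank=rank,
                     sample_types=("mock",), max_dilution=None)
    if cvtab.empty:
        raise ValueError("no dilution strata with >= 2 replicates")
    level_copies = {}
    md = metadata.loc[metadata.index.intersection(relabund.sample_ids)]
    for level, sids in md.groupby("dilution_factor").groups.items():
        sids = qpcr.index.intersection(sids)
        level_copies[level] = float(qpcr.loc[sids, "copies_per_ul"].mean()) \
            if len(sids) else np.nan
    rows = []
    for _, r in cvtab.iterrows():
        copies = level_copies.get(r["stratum"], np.nan)
        if (np.isnan(r["cv_pct"]) or r["cv_pct"] <= 0
                or r["mean_ra"] < min_mean_ra
                or r["n_detected"] < min_detected
                or not np.isfinite(copies) or copies <= 0):
            continue
        rows.append(dict(taxon=r["taxon"], dilution_factor=float(r["stratum"]),
                         mean_ra=r["mean_ra"], cv_pct=r["cv_pct"],
                         copies_per_ul=copies, n_detected=r["n_detected"]))
    out = pd.DataFrame(rows, columns=["taxon", "dilution_factor", "mean_ra",
                                      "cv_pct", "copies_per_ul", "n_detected"])
    if out.empty:
        raise ValueError("no rows pass the CV-dataset inclusion filters")
    return out


@dataclass(frozen=True)
class VariationModel:
    """OLS fit of log10(variability) on log10 biomass and log10 abundance.

    ``params`` is (intercept, slope on log10 copies/uL, slope on log10
    mean relative abundance).  ``ra_unit`` records whether abundance
    entered the fit as 'percent' or 'fraction'; predictions use the same
    convention.  ``response`` is 'cv' (percent CV) or 'sd'.
    """

    params: tuple[float, float, float]
    bse: tuple[float, float, float]
    tvalues: tuple[float, float, float]
    pvalues: tuple[float, float, float]
    resid_se: float
    r_squared: float
    adj_r_squared: float
    f_stat: float
    df_model: int
    df_resid: int
    n_obs: int
    ra_unit: str = "percent"
    response: str = "cv"

    def conf_int(self, alpha: float = 0.05) -> np.ndarray:
        from scipy.stats import t
        q = t.ppf(1 - alpha / 2, self.df_resid)
        p, se = np.asarray(self.params), np.asarray(self.bse)
        return np.column_stack([p - q * se, p + q * se])


def fit_variation_model(ds: pd.DataFrame, ra_unit: str = "percent",
                        response: str = "cv") -> VariationModel:
    """Ordinary least squares for the variance prediction model.

    ``log10(response) ~ log10(copies/uL) + log10(mean RA)`` where the
    response is the percent CV by default (``response='sd'`` uses the SD
    of relative abundances instead, requiring an ``sd_ra`` column).
    """
    if ra_unit not in ("percent", "fraction"):
        raise ValueError("ra_unit must be 'percent' or 'fraction'")
    if response == "cv":
        y_raw = ds["cv_pct"].to_numpy(dtype=float)
    elif response == "sd":
        y_raw = ds["sd_ra"].to_numpy(dtype=float)
    else:
        raise ValueError("response must be 'cv' or 'sd'")
    if len(ds) < 4:
        raise ValueError("need at least 4 rows")
    ra = ds["mean_ra"].to_numpy(dtype=float)
    if ra_unit == "percent":
        ra = ra * 100.0
    copies = ds["copies_per_ul"].to_numpy(dtype=float)
    if (y_raw <= 0).any() or (ra <= 0).any() or (copies <= 0).any():
        raise ValueError("all logged quantities must be positive")
    X = sm.add_constant(np.column_stack([np.log10(copies), np.log10(ra)]))
    if np.linalg.matrix_rank(X) < 3:
        raise ValueError("collinear predictors")
    with np.errstate(divide="ignore", invalid="ignore"):
        res = sm.OLS(np.log10(y_raw), X).fit()
        r2 = float(res.rsquared)
        adj = float(res.rsquared_adj)
        f = float(res.fvalue)
    # a constant response has zero total variance; report R^2 = 0, not -inf
    if not np.isfinite(r2):
        r2, adj, f = 0.0, 0.0, 0.0
    return VariationModel(
        params=tuple(res.params), bse=tuple(res.bse),
        tvalues=tuple(res.tvalues), pvalues=tuple(res.pvalues),
        resid_se=float(np.sqrt(res.mse_resid)),
        r_squared=r2, adj_r_squared=adj,
        f_stat=f, df_model=int(res.df_model),
        df_resid=int(res.df_resid), n_obs=int(res.nobs),
        ra_unit=ra_unit, response=response)


def predict_variation(model: VariationModel, copies_per_ul: float,
                      mean_ra: float) -> float:
    """Back-transformed model prediction.

    ``10**(b0 + b1 log10(copies) + b2 log10(ra))`` with ``mean_ra`` given
    in the model's declared unit (percent by default).
    """
    if copies_per_ul <= 0 or mean_ra <= 0:
        raise ValueError("copies and abundance must be positive")
    b0, b1, b2 = model.params
    return float(10.0 ** (b0 + b1 * math.log10(copies_per_ul)
                          + b2 * math.log10(mean_ra)))


def prediction_grid(model: VariationModel,
                    copies=DEFAULT_GRID_COPIES,
                    mean_ra=DEFAULT_GRID_RA_PERCENT) -> pd.DataFrame:
    """Predictions over the copies x abundance cross-product.

    Default grid: copies/uL in {10, 1e3, 1e5} (low / medium / high
    biomass) by mean relative abundance in {1, 5, 10, 25, 50} (model
    units, percent by default).  Rows are copies, columns abundances.
    """
    grid = np.array([[predict_variation(model, c, r) for r in mean_ra]
                     for c in copies])
    return pd.DataFrame(grid, index=pd.Index(copies, name="copies_per_ul"),
                        columns=pd.Index(mean_ra, name=f"mean_ra_{model.ra_unit}"))
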