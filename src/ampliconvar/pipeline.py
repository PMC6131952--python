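"""End-to-end study analysis: QC -> variability -> distances -> biomass model.

`run_pipeline` reproduces the full analysis narrative on any input study,
synthetic or user-supplied, and returns a JSON-serialisable report whose
sections are either populated or explicitly marked skipped with a reason.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as avio
from . import simulate as sim
from .biomass import (build_cv_dataset, expected_copies, fit_standard_curve,
                      fit_variation_model, prediction_grid, quantify)
from .distance import (distance_groups, pairwise_distances, pcoa,
                       permanova_factors)
from .qc import qc_pipeline
from .variability import (cv_abundance_association, cv_table, icc_by_taxon,
                          levey_jennings, mean_intra_cv, shannon)

__all__ = ["PipelineConfig", "run_pipeline", "simulate_from_config"]


@dataclass
class PipelineConfig:
    """All knobs of the study-level pipeline.

    Either the three input paths or a ``simulate`` block must be given.
    Defaults are the pipeline's standard choices: contaminant-score
    threshold 0.1, at most 2 negative controls surviving the depth
    filter, 999 PERMANOVA permutations.
    """

    counts: str | None = None
    metadata: str | None = None
    qpcr: str | None = None
    standards: str | None = None
    simulate: dict | None = None

    contaminant_threshold: float = 0.1
    max_negatives_retained: int = 2
    depth_override: int | None = None
    rarefaction_seed: int = 0
    ranks: tuple[str, ...] = ("family", "genus")
    cv_rank: str = "genus"
    distance_metric: str = "bray_curtis"
    permutations: int = 999
    permutation_seed: int = 0
    grid_copies: tuple[float, ...] = (10.0, 1e3, 1e5)
    grid_ra: tuple[float, ...] = (1.0, 5.0, 10.0, 25.0, 50.0)
    outdir: str | None = None
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.contaminant_threshold <= 1:
            raise ValueError("contaminant_threshold must be in [0, 1]")
        if self.permutations < 99:
            raise ValueError("permutations must be >= 99")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        cfg = avio.load_config(path)
        for key in ("ranks", "grid_copies", "grid_ra"):
            if key in cfg and isinstance(cfg[key], list):
                cfg[key] = tuple(cfg[key])
        return cls(**cfg)


def simulate_from_config(block: dict | None, seed: int = 0) -> sim.SyntheticStudy:
    """Build a synthetic study from the ``simulate`` config block."""
    block = dict(block or {})
    design_name = block.pop("design", "full")
    seed = int(block.pop("seed", seed))
    spec = sim.mock_community(
        n_taxa=int(block.pop("n_taxa", 33)),
        proportions=block.pop("proportions", "uniform"),
        decay=float(block.pop("decay", 0.7)),
        stock_copies_per_ul=float(block.pop("stock_copies_per_ul", 7520.0)))
    noise = sim.NoiseModel(**block.pop("noise", {}))
    if block:
        raise ValueError(f"unknown simulate keys: {sorted(block)}")
    if design_name == "full":
        design = sim.full_study_design(seed=seed)
        return sim.simulate_study(spec, design, noise)
    if design_name == "dilution":
        return sim.simulate_dilution_series(spec, sim.dilution_design(seed=seed),
                                            noise)
    raise ValueError("simulate.design must be 'full' or 'dilution'")


def _load_inputs(config: PipelineConfig):
    if config.counts:
        if not config.metadata:
            raise ValueError("metadata path required alongside counts")
        table = avio.read_feature_table(config.counts)
        metadata = avio.read_metadata(config.metadata)
        qpcr_wells = avio.read_qpcr_wells(config.qpcr) if config.qpcr else None
        standards = avio.read_standards(config.standards) if config.standards else None
        return table, metadata, qpcr_wells, standards
    study = simulate_from_config(config.simulate, config.seed)
    return study.counts, study.metadata, study.qpcr_wells, study.standards


def _variability_section(relabund, metadata, ranks, cv_rank):
    section = {"per_rank": {}}
    tables = {}
    for rank in ranks:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            intra = cv_table(relabund, metadata, stratify_by="run", rank=rank)
            inter = cv_table(relabund, metadata, stratify_by="none", rank=rank)
        summary = mean_intra_cv(intra)
        _, icc_mean = icc_by_taxon(relabund, metadata, rank=rank)
        inter_by_taxon = inter.set_index("taxon")["cv_pct"]
        abundant = summary[summary["mean_ra"] > 0.01]
        entry = {
            "icc_mean": icc_mean,
            "n_taxa": int(len(summary)),
            "mean_intra_cv_range_abundant": [
                float(abundant["mean_cv"].min()) if len(abundant) else None,
                float(abundant["mean_cv"].max()) if len(abundant) else None],
            "inter_cv_range_abundant": [
                float(inter_by_taxon.reindex(abundant.index).min()) if len(abundant) else None,
                float(inter_by_taxon.reindex(abundant.index).max()) if len(abundant) else None],
        }
        try:
            rho, p = cv_abundance_association(mean_intra_cv(inter))
            entry["cv_abundance_spearman"] = {"rho": rho, "p": p}
        except ValueError as exc:
            entry["cv_abundance_spearman"] = {"skipped": str(exc)}
        section["per_rank"][rank] = entry
        tables[rank] = {"intra": intra, "inter": inter, "summary": summary}
    _, flags = levey_jennings(relabund, metadata, rank=cv_rank)
    section["levey_jennings_flagged"] = int(flags["flagged"].sum())
    section["levey_jennings_total"] = int(len(flags))
    return section, tables, flags


def _distance_section(relabund, metadata, metric, permutations, seed):
    md = metadata.loc[list(relabund.sample_ids)]
    undil = md["dilution_factor"].isna() | (md["dilution_factor"] <= 1)
    ids = md.index[(md["sample_type"].isin(["mock", "stool"])) & undil]
    if len(ids) < 3:
        return {"skipped": "fewer than 3 undiluted mock/stool samples"}, None
    sub = relabund.select_samples(ids)
    dm = pairwise_distances(sub, metric)
    section = {"metric": metric, "n_samples": dm.n}
    ord_res = pcoa(dm, n_axes=2)
    section["pcoa_proportion_explained"] = [float(x) for x in
                                            ord_res.proportion_explained]
    factors = [f for f in ("sample_type", "run_id")
               if metadata.loc[ids, f].nunique() > 1]
    if factors:
        results = permanova_factors(dm, metadata, factors, permutations, seed)
        section["permanova"] = {f: {"r_squared": r.r_squared,
                                    "pseudo_f": r.pseudo_f,
                                    "p_value": r.p_value}
                                for f, r in results.items()}
    else:
        section["permanova"] = {"skipped": "no factor with >= 2 levels"}
    groups = distance_groups(dm, metadata)
    if len(groups.empty) < 3:
        section["distance_groups"] = groups.summary().to_dict(orient="index")
    else:
        section["distance_groups"] = {"skipped": "no specimen-labelled samples"}
    return section, dm


def _biomass_section(relabund, rarefied, metadata, qpcr_wells, standards,
                     cv_rank, grid_copies, grid_ra):
    md = metadata.loc[list(relabund.sample_ids)]
    diluted_runs = md.loc[md["dilution_factor"] > 1, "run_id"].unique()
    if qpcr_wells is None or len(qpcr_wells) == 0:
        return {"skipped": "no qPCR data provided"}, None, None
    if len(diluted_runs) == 0:
        return {"skipped": "no dilution-series samples survive QC"}, None, None
    run_id = diluted_runs[0]
    ids = md.index[(md["run_id"] == run_id) & md["dilution_factor"].notna()]
    section = {"dilution_run": str(run_id), "n_samples": int(len(ids))}

    if standards is not None and len(standards):
        curve = fit_standard_curve(standards)
        section["standard_curve"] = {
            "slope": curve.slope, "intercept": curve.intercept,
            "r_squared": curve.r_squared, "efficiency": curve.efficiency}
        qres = quantify(qpcr_wells[qpcr_wells["sample_id"].isin(ids)], curve)
        qpcr = qres[["copies_per_ul"]]
    else:
        section["standard_curve"] = {"skipped": "no standards provided"}
        qpcr = (qpcr_wells[qpcr_wells["sample_id"].isin(ids)]
                .groupby("sample_id")[["copies_per_ul"]].mean()
                if "copies_per_ul" in qpcr_wells.columns else None)
    if qpcr is None or qpcr.empty:
        return {"skipped": "qPCR data do not cover the dilution run"}, None, None

    sub_md = md.loc[ids]
    levels = sorted(sub_md["dilution_factor"].unique())
    measured = []
    for level in levels:
        lids = qpcr.index.intersection(sub_md.index[sub_md["dilution_factor"] == level])
        measured.append(float(qpcr.loc[lids, "copies_per_ul"].mean())
                        if len(lids) else np.nan)
    if levels and levels[0] == 1.0:
        calib = expected_copies(levels, measured)
        logs = np.log10(calib[["naive_expected", "measured"]].dropna())
        r = float(np.corrcoef(logs["naive_expected"], logs["measured"])[0, 1]) \
            if len(logs) > 2 else None
        section["calibration"] = {"pearson_r_log10": r,
                                  "levels": calib.reset_index().to_dict("records")}
    else:
        calib = None
        section["calibration"] = {"skipped": "stock (factor 1) not present post-QC"}

    sub = relabund.select_samples(relabund.sample_ids.intersection(ids))
    ds = build_cv_dataset(sub, metadata, qpcr, rank=cv_rank)
    model = fit_variation_model(ds)
    section["variation_model"] = {
        "intercept": model.params[0],
        "slope_log10_copies": model.params[1],
        "slope_log10_mean_ra": model.params[2],
        "bse": list(model.bse), "pvalues": list(model.pvalues),
        "resid_se": model.resid_se, "r_squared": model.r_squared,
        "adj_r_squared": model.adj_r_squared, "f_stat": model.f_stat,
        "df": [model.df_model, model.df_resid], "n_obs": model.n_obs,
        "ra_unit": model.ra_unit, "response": model.response}
    grid = prediction_grid(model, grid_copies, grid_ra)
    section["prediction_grid"] = grid.reset_index().to_dict("records")

    rare_ids = rarefied.sample_ids.intersection(ids)
    if len(rare_ids):
        H = shannon(rarefied.select_samples(rare_ids))
        by_level = (pd.DataFrame({"H": H,
                                  "level": sub_md.loc[list(rare_ids), "dilution_factor"]})
                    .groupby("level")["H"].mean())
        section["shannon_by_level"] = {float(k): float(v) for k, v in by_level.items()}
    return section, ds, model


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis and (optionally) write all artifacts."""
    table, metadata, qpcr_wells, standards = _load_inputs(config)
    report: dict = {"seeds": {"study": config.seed,
                              "rarefaction": config.rarefaction_seed,
                              "permutation": config.permutation_seed}}

    qc = qc_pipeline(table, metadata, config.contaminant_threshold,
                     config.max_negatives_retained, config.depth_override,
                     config.rarefaction_seed)
    report["qc"] = qc["report"]
    relabund, rarefied = qc["relabund"], qc["rarefied"]
    kept_md = qc["metadata"]

    try:
        section, cv_tables, lj_flags = _variability_section(
            relabund, kept_md, config.ranks, config.cv_rank)
        report["variability"] = section
    except (ValueError, KeyError) as exc:
        report["variability"] = {"skipped": str(exc)}
        cv_tables, lj_flags = {}, None

    try:
        section, dm = _distance_section(relabund, kept_md,
                                        config.distance_metric,
                                        config.permutations,
                                        config.permutation_seed)
        report["distance"] = section
    except (ValueError, KeyError) as exc:
        report["distance"] = {"skipped": str(exc)}
        dm = None

    try:
        section, cv_ds, model = _biomass_section(
            relabund, rarefied, kept_md, qpcr_wells, standards,
            config.cv_rank, config.grid_copies, config.grid_ra)
        report["biomass"] = section
    except (ValueError, KeyError) as exc:
        report["biomass"] = {"skipped": str(exc)}
        cv_ds = model = None

    if config.outdir:
        out = Path(config.outdir)
        out.mkdir(parents=True, exist_ok=True)
        avio.write_json(report, out / "report.json")
        avio.write_feature_table(qc["table"], out / "filtered_counts.tsv")
        avio.write_metadata(kept_md, out / "filtered_metadata.tsv")
        for rank, tabs in cv_tables.items():
            tabs["intra"].to_csv(out / f"cv_intra_{rank}.tsv", sep="\t", index=False)
            tabs["inter"].to_csv(out / f"cv_inter_{rank}.tsv", sep="\t", index=False)
        if lj_flags is not None:
            lj_flags.to_csv(out / "levey_jennings_flags.tsv", sep="\t", index=False)
        if dm is not None:
            dm.as_frame().to_csv(out / f"distances_{dm.metric}.tsv", sep="\t")
        if cv_ds is not None:
            cv_ds.to_csv(out / "cv_dataset.tsv", sep="\t", index=False)
        if model is not None:
            grid = prediction_grid(model, config.grid_copies, config.grid_ra)
            grid.to_csv(out / "prediction_grid.tsv", sep="\t")
    return report
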