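"""Optional figures: composition bars, PCoA, Levey-Jennings, dilution curves."""

from __future__ import annotations

import numpy as np
import pandas as pd

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

__all__ = ["composition_bars", "pcoa_plot", "levey_jennings_plot",
           "dilution_curve_plot"]


def composition_bars(relabund, metadata, path, top_n: int = 12):
    """Stacked relative-abundance bars, samples ordered by run."""
    order = metadata.loc[list(relabund.sample_ids)].sort_values("run_id").index
    block = relabund.counts[list(order)]
    top = block.mean(axis=1).nlargest(top_n).index
    rest = block.drop(index=top).sum(axis=0)
    data = pd.concat([block.loc[top], rest.to_frame("other").T])
    fig, ax = plt.subplots(figsize=(max(6, 0.08 * len(order)), 4))
    bottom = np.zeros(len(order))
    for taxon in data.index:
        vals = data.loc[taxon].to_numpy()
        ax.bar(range(len(order)), vals, bottom=bottom, width=1.0,
               label=str(taxon).split(";")[-1].strip())
        bottom += vals
    ax.set_xlim(-0.5, len(order) - 0.5)
    ax.set_ylabel("relative abundance")
    ax.set_xticks([])
    ax.legend(fontsize=6, loc="center left", bbox_to_anchor=(1, 0.5))
    fig.savefig(path, bbox_inches="tight", dpi=150)
    plt.close(fig)


def pcoa_plot(result, metadata, path, color_by: str = "sample_type"):
    coords = result.coordinates
    groups = metadata.loc[coords.index, color_by]
    fig, ax = plt.subplots(figsize=(5, 4))
    for g in groups.unique():
        sel = groups == g
        ax.scatter(coords.loc[sel, "PC1"], coords.loc[sel, "PC2"], s=12, label=str(g))
    pe = result.proportion_explained
    ax.set_xlabel(f"PC1 [{100 * pe[0]:.1f}%]")
    ax.set_ylabel(f"PC2 [{100 * pe[1]:.1f}%]" if len(pe) > 1 else "PC2")
    ax.legend(fontsize=8)
    fig.savefig(path, bbox_inches="tight", dpi=150)
    plt.close(fig)


def levey_jennings_plot(stats, flags, taxon, path, k_sd: float = 2.0):
    """One taxon's control chart: mean, +/-1 SD, +/-2 SD, flagged points."""
    sub = flags[flags["taxon"] == taxon].reset_index(drop=True)
    m, s = stats.at[taxon, "mean"], stats.at[taxon, "sd"]
    fig, ax = plt.subplots(figsize=(7, 3))
    x = np.arange(len(sub))
    ax.plot(x, sub["value"], "o-", ms=3, lw=0.8, color="gray")
    ok = ~sub["flagged"]
    ax.plot(x[~ok.to_numpy()], sub.loc[~ok, "value"], "o", ms=5, color="red")
    ax.axhline(m, color="k")
    for k, style in ((1, "--"), (k_sd, ":")):
        ax.axhline(m + k * s, color="k", ls=style, lw=0.8)
        ax.axhline(m - k * s, color="k", ls=style, lw=0.8)
    ax.set_title(str(taxon).split(";")[-1].strip(), fontsize=9)
    ax.set_ylabel("relative abundance")
    fig.savefig(path, bbox_inches="tight", dpi=150)
    plt.close(fig)


def dilution_curve_plot(calibration, path):
    """Measured vs. naive and sequential expected copies, log-log."""
    df = calibration.reset_index()
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.plot(df["dilution_factor"], df["naive_expected"], "s--", label="naive expected")
    ax.plot(df["dilution_factor"], df["sequential_expected"], "^--",
            label="sequential expected")
    ax.plot(df["dilution_factor"], df["measured"], "o-", label="measured")
    ax.set_xscale("log")
    ax.set_yscale("log")
    ax.set_xlabel("dilution factor")
    ax.set_ylabel("16S copies/uL")
    ax.legend(fontsize=8)
    fig.savefig(path, bbox_inches="tight", dpi=150)
    plt.close(fig)
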