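"""Report figures: D distributions, FLK H_T scatter, PCA scan, DAPC."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

_CLASS_COLORS = {"syn": "#c23b22", "nonsyn": "#e89bb0"}


def plot_d_density(records: pd.DataFrame, path: str | Path) -> None:
    """Per-cluster density histograms of syn/nonsyn Tajima's D."""
    clusters = sorted(records["cluster"].unique())
    fig, axes = plt.subplots(1, len(clusters), figsize=(4 * len(clusters), 3),
                             sharex=True, sharey=True)
    axes = np.atleast_1d(axes)
    for ax, cluster in zip(axes, clusters):
        for sc, color in _CLASS_COLORS.items():
            d = records.query("cluster == @cluster and site_class == @sc")["d"].dropna()
            if len(d):
                ax.hist(d, bins=20, density=True, alpha=0.55, color=color, label=sc)
        ax.axvline(0, color="grey", lw=0.8, ls="--")
        ax.set_title(cluster)
        ax.set_xlabel("Tajima's D")
    axes[0].set_ylabel("density")
    axes[0].legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_d_bands(summary: pd.DataFrame, path: str | Path) -> None:
    """Stacked fractions of genes with D > 1, -1..1, D < -1."""
    sub = summary.sort_values(["cluster", "site_class"])
    labels = [f"{r.cluster}\n{r.site_class}" for r in sub.itertuples()]
    x = np.arange(len(sub))
    fig, ax = plt.subplots(figsize=(1.1 * len(sub) + 1, 3))
    bottom = np.zeros(len(sub))
    for col, color, lab in (
        ("frac_d_lt_m1", "#4878d0", "D < -1"),
        ("frac_d_mid", "#d0d0d0", "-1..1"),
        ("frac_d_gt1", "#d65f5f", "D > 1"),
    ):
        vals = sub[col].fillna(0).to_numpy()
        ax.bar(x, vals, bottom=bottom, color=color, label=lab)
        bottom += vals
    ax.set_xticks(x, labels, fontsize=8)
    ax.set_ylabel("fraction of genes")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_flk(scan: pd.DataFrame, path: str | Path) -> None:
    """T_FLK against total heterozygosity with the 0.995 threshold curve."""
    runs = sorted(scan["run"].unique())
    fig, axes = plt.subplots(1, len(runs), figsize=(4 * len(runs), 3), sharey=True)
    axes = np.atleast_1d(axes)
    for ax, run in zip(axes, runs):
        sub = scan[scan["run"] == run].sort_values("h_t")
        color = np.where(sub["significant"], "#e87d1e", "#9a9a9a")
        ax.scatter(sub["h_t"], sub["t_flk"], s=8, c=color)
        ax.plot(sub["h_t"], sub["threshold"], color="black", lw=1)
        ax.set_title(run, fontsize=8)
        ax.set_xlabel("$H_T$")
    axes[0].set_ylabel("$T_{FLK}$")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_pca_scan(table: pd.DataFrame, path: str | Path) -> None:
    """-log10 p per SNP, discoveries highlighted."""
    fig, ax = plt.subplots(figsize=(6, 3))
    logp = -np.log10(np.maximum(table["p"], 1e-300))
    color = np.where(table["significant"], "#e87d1e", "#9a9a9a")
    ax.scatter(np.arange(len(table)), logp, s=8, c=color)
    ax.set_xlabel("SNP index")
    ax.set_ylabel("$-\\log_{10} p$")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_dapc(coords: pd.DataFrame, path: str | Path, grid: float = 5.0) -> None:
    """Discriminant scatter with one colour per cluster."""
    fig, ax = plt.subplots(figsize=(4, 4))
    y = coords["LD2"] if "LD2" in coords else pd.Series(0.0, index=coords.index)
    for cluster, sub in coords.groupby("cluster"):
        ax.scatter(sub["LD1"], y.loc[sub.index], s=14, label=str(cluster))
    ax.set_xlabel("LD1")
    ax.set_ylabel("LD2" if "LD2" in coords else "")
    ax.xaxis.set_major_locator(plt.MultipleLocator(grid))
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
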