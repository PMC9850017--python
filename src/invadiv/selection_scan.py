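"""Sign-based classification of genes as under balancing or directional
selection, and the supporting group comparisons.

A gene shows a *sign* of elevated (lowered) Tajima's D in a cluster when
D > 1.5 (< -1.5), or D is in the 95th (5th) percentile of the cluster x
class distribution, or D is significantly higher (lower) than the neutral
coalescent expectation. The verdict requires >= 2 of the 3 signs in one
cluster and >= 1 sign in at least one other cluster, evaluated within a
site class. The pi-95th-percentile status is attached as an annotation and
never gates the verdict.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import UndefinedStatistic
from .neutral_null import NullCache, empirical_p

D_CUT_DEFAULT = 1.5
Q_LOW, Q_HIGH = 0.05, 0.95


@dataclass
class SelectionSigns:
    gene: str
    cluster: str
    site_class: str
    direction: str  # "high" | "low"
    extreme: bool = False
    percentile: bool = False
    significant: bool = False
    pi_pctl: bool = False  # annotation only

    @property
    def sign_count(self) -> int:
        return int(self.extreme) + int(self.percentile) + int(self.significant)


@dataclass
class ClassifiedGene:
    gene: str
    verdict: str  # "balancing" | "directional" | "none"
    anchor_cluster: str | None = None
    supporting_clusters: list[str] = field(default_factory=list)
    carrying_classes: list[str] = field(default_factory=list)
    pi_pctl_flags: dict[str, bool] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Flags
# ---------------------------------------------------------------------------

def percentile_flags(
    records: pd.DataFrame,
    value: str = "d",
    q_low: float = Q_LOW,
    q_high: float = Q_HIGH,
) -> pd.DataFrame:
    """Flag genes at or beyond the empirical q_low/q_high quantiles.

    Quantiles are type-7 (linear interpolation, numpy default) computed per
    (cluster, site_class) over genes with defined values; membership uses
    >= / <=. When all values are identical no flags are raised.
    """
    out = records.copy()
    out["flag_high"] = False
    out["flag_low"] = False
    for (_, _), grp in records.groupby(["cluster", "site_class"]):
        vals = grp[value].dropna()
        if vals.empty or vals.nunique() == 1:
            continue
        hi = np.quantile(vals, q_high)  # numpy default = type-7 linear
        lo = np.quantile(vals, q_low)
        out.loc[grp.index, "flag_high"] = grp[value] >= hi
        out.loc[grp.index, "flag_low"] = grp[value] <= lo
    out.loc[records[value].isna(), ["flag_high", "flag_low"]] = False
    return out


def threshold_flags(records: pd.DataFrame, d_cut: float = D_CUT_DEFAULT) -> pd.DataFrame:
    """Strict-inequality |D| threshold flags (D > d_cut high, D < -d_cut low)."""
    if d_cut <= 0:
        raise ValueError("d_cut must be > 0")
    out = records.copy()
    d = records["d"]
    out["flag_high"] = (d > d_cut).fillna(False)
    out["flag_low"] = (d < -d_cut).fillna(False)
    return out


def coalescent_flags(
    records: pd.DataFrame, cache: NullCache, alpha: float = 0.05
) -> pd.DataFrame:
    """Flag genes whose D is significantly above/below the neutral null.

    Significance is the one-sided empirical p (direction of the observed
    sign) against the per-gene coalescent null at the gene's (n, S);
    no multiple-testing correction is applied (by design).
    """
    out = records.copy()
    out["null_p"] = np.nan
    out["flag_high"] = False
    out["flag_low"] = False
    for i, row in records.iterrows():
        if np.isnan(row["d"]) or row["S"] == 0 or row["n_chrom"] < 2:
            continue
        null = cache.get(int(row["n_chrom"]), int(row["S"]), row.get("pi_total", np.nan))
        try:
            p = empirical_p(float(row["d"]), null)
        except UndefinedStatistic:
            continue
        out.loc[i, "null_p"] = p
        if p <= alpha:
            if row["d"] > 0:
                out.loc[i, "flag_high"] = True
            elif row["d"] < 0:
                out.loc[i, "flag_low"] = True
    return out


def build_signs(
    records: pd.DataFrame,
    cache: NullCache | None = None,
    d_cut: float = D_CUT_DEFAULT,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Assemble the three signs (+ pi annotation) per gene x cluster x class.

    Returns a frame with boolean columns extreme_{high,low},
    pctl_{high,low}, signif_{high,low}, pi_pctl_high and the counts
    signs_high / signs_low.
    """
    thr = threshold_flags(records, d_cut=d_cut)
    pct = percentile_flags(records, value="d")
    pi_pct = percentile_flags(records, value="pi")
    out = records.copy()
    out["extreme_high"] = thr["flag_high"]
    out["extreme_low"] = thr["flag_low"]
    out["pctl_high"] = pct["flag_high"]
    out["pctl_low"] = pct["flag_low"]
    out["pi_pctl_high"] = pi_pct["flag_high"]
    if cache is not None:
        sig = coalescent_flags(records, cache, alpha=alpha)
        out["signif_high"] = sig["flag_high"]
        out["signif_low"] = sig["flag_low"]
        out["null_p"] = sig["null_p"]
    else:
        out["signif_high"] = False
        out["signif_low"] = False
        out["null_p"] = np.nan
    out["signs_high"] = (
        out["extreme_high"].astype(int)
        + out["pctl_high"].astype(int)
        + out["signif_high"].astype(int)
    )
    out["signs_low"] = (
        out["extreme_low"].astype(int)
        + out["pctl_low"].astype(int)
        + out["signif_low"].astype(int)
    )
    return out


# ---------------------------------------------------------------------------
# 2-of-3 classification
# ---------------------------------------------------------------------------

def _classify(signs: pd.DataFrame, direction: str, verdict: str,
              same_class: bool = True) -> list[ClassifiedGene]:
    col = f"signs_{direction}"
    results = []
    for gene, grp in signs.groupby("gene", sort=True):
        best: ClassifiedGene | None = None
        classes = grp["site_class"].unique()
        scopes = [(sc, grp[grp["site_class"] == sc]) for sc in classes]
        if not same_class:
            scopes = [("any", grp)]
        carrying = []
        anchor = None
        supporting: list[str] = []
        for sc, sub in scopes:
            per_cluster = sub.groupby("cluster")[col].max()
            anchors = per_cluster[per_cluster >= 2].index.tolist()
            if not anchors:
                continue
            others = per_cluster[(per_cluster >= 1)].index.tolist()
            for a in anchors:
                rest = [c for c in others if c != a]
                if rest:
                    carrying.append(sc)
                    if anchor is None:
                        anchor, supporting = a, rest
                    break
        if anchor is not None:
            pi_flags = dict(
                grp.groupby("cluster")["pi_pctl_high"].max().astype(bool)
            )
            best = ClassifiedGene(
                gene=gene, verdict=verdict, anchor_cluster=anchor,
                supporting_clusters=supporting, carrying_classes=carrying,
                pi_pctl_flags=pi_flags,
            )
        results.append(
            best if best is not None else ClassifiedGene(gene=gene, verdict="none")
        )
    return results


def classify_balancing(signs: pd.DataFrame, same_class: bool = True) -> list[ClassifiedGene]:
    """Genes with >= 2 elevated-D signs in one cluster and >= 1 in another."""
    return _classify(signs, "high", "balancing", same_class=same_class)


def classify_directional(signs: pd.DataFrame, same_class: bool = True) -> list[ClassifiedGene]:
    """Mirror of classify_balancing on lowered-D signs."""
    return _classify(signs, "low", "directional", same_class=same_class)


def single_cluster_extremes(signs: pd.DataFrame) -> dict[tuple[str, str], list[str]]:
    """Genes in the 5th percentile in exactly one cluster, per (cluster, class)."""
    out: dict[tuple[str, str], list[str]] = {}
    if signs.empty:
        return out
    for sc, sub in signs.groupby("site_class"):
        flagged = sub[sub["pctl_low"]]
        per_gene = flagged.groupby("gene")["cluster"].nunique()
        solo = set(per_gene[per_gene == 1].index)
        for _, row in flagged.iterrows():
            if row["gene"] in solo:
                out.setdefault((row["cluster"], sc), []).append(row["gene"])
    return {k: sorted(v) for k, v in out.items()}


def compare_selected_vs_rest(
    records: pd.DataFrame, selected: set[str], value: str = "pi"
) -> pd.DataFrame:
    """Mann-Whitney U of pi between selected genes and the rest.

    Two-sided; exact p by enumeration when min(n, m) <= 8, else the normal
    approximation with tie correction. One row per cluster x site class.
    """
    rows = []
    for (cluster, sc), grp in records.groupby(["cluster", "site_class"]):
        sel = grp[grp["gene"].isin(selected)][value].dropna().to_numpy()
        rest = grp[~grp["gene"].isin(selected)][value].dropna().to_numpy()
        if sel.size == 0 or rest.size == 0:
            raise UndefinedStatistic(
                f"empty group in Mann-Whitney comparison ({cluster}, {sc})"
            )
        method = "exact" if min(sel.size, rest.size) <= 8 else "asymptotic"
        if method == "exact" and _has_cross_ties(sel, rest):
            method = "asymptotic"
        res = stats.mannwhitneyu(sel, rest, alternative="two-sided", method=method)
        rows.append(
            {"cluster": cluster, "site_class": sc, "U": float(res.statistic),
             "p": float(res.pvalue), "n_selected": sel.size, "n_rest": rest.size}
        )
    return pd.DataFrame(rows)


def _has_cross_ties(a: np.ndarray, b: np.ndarray) -> bool:
    return np.intersect1d(a, b).size > 0 or len(np.unique(a)) < a.size or len(np.unique(b)) < b.size
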