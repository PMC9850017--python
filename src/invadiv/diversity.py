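"""Per-gene, per-cluster nucleotide diversity and Tajima's D.

Statistics are computed from unphased genotype allele counts (haplotypes are
never reconstructed): for site frequency spectrum statistics the allele
frequencies carry all the information pi, theta_W and D need.

Conventions
-----------
* ``pi`` and ``theta_w`` in a :class:`DiversityRecord` are per-site values,
  normalised by the class's potential site count L_class (Nei–Gojobori exact
  counting by default, or the crude 1/4 syn : 3/4 nonsyn split).
* Per-site missingness makes the chromosome count n vary across sites;
  site-level heterozygosity uses each site's own n, while the Tajima
  constants are evaluated at a per-fragment summary n (median by default).
* D is undefined when S = 0 (or the variance term vanishes); undefined
  records carry ``d = nan`` and are excluded from summaries with a count.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import (
    MISSING,
    ClusterMap,
    GeneFragment,
    GenotypeMatrix,
    SiteEffect,
    UndefinedStatistic,
)
from .variant_io import nei_gojobori_site_counts

SITE_CLASSES = ("syn", "nonsyn")


@dataclass
class DiversityRecord:
    gene: str
    cluster: str
    site_class: str
    S: int
    n_chrom: int
    pi: float            # per-site, / L_class
    theta_w: float       # per-site, / L_class
    d: float             # Tajima's D, nan when undefined
    L_class: float
    pi_total: float = 0.0  # unnormalised sum of site heterozygosities


# ---------------------------------------------------------------------------
# Elementary statistics
# ---------------------------------------------------------------------------

def site_pi(alt_count: int, n: int) -> float:
    """Unbiased per-site heterozygosity 2 p (1-p) n/(n-1).

    Equals the mean number of differences over all n(n-1)/2 chromosome pairs
    at the site.
    """
    if n < 2:
        raise UndefinedStatistic("site_pi needs n >= 2 chromosomes")
    if not 0 <= alt_count <= n:
        raise ValueError("alt_count must be in [0, n]")
    p = alt_count / n
    return 2.0 * p * (1.0 - p) * n / (n - 1.0)


@lru_cache(maxsize=4096)
def harmonic(n: int, power: int = 1) -> float:
    """a1 = sum 1/i (power=1) or a2 = sum 1/i^2 (power=2), i = 1..n-1."""
    return float(sum(1.0 / i**power for i in range(1, n)))


@lru_cache(maxsize=1024)
def tajima_constants(n: int) -> dict[str, float]:
    """The b1, b2, c1, c2, e1, e2 normalising constants (Tajima 1989)."""
    if n < 2:
        raise UndefinedStatistic("Tajima constants need n >= 2")
    a1 = harmonic(n, 1)
    a2 = harmonic(n, 2)
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / (a1 * a1)
    e1 = c1 / a1
    e2 = c2 / (a1 * a1 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2, "c1": c1, "c2": c2, "e1": e1, "e2": e2}


def tajima_d(pi_total: float, S: int, n: int) -> float:
    """Tajima's D from total pairwise diversity, segregating sites and n.

    Returns nan when S = 0 or the variance term is zero.
    """
    if S == 0 or n < 2:
        return float("nan")
    k = tajima_constants(n)
    var = k["e1"] * S + k["e2"] * S * (S - 1)
    if var <= 0:
        return float("nan")
    return (pi_total - S / k["a1"]) / math.sqrt(var)


def sfs_statistics(counts: np.ndarray, n: int) -> tuple[int, float, float, float]:
    """(S, pi_total, theta_w_total, D) from derived-allele counts at n chroms.

    Monomorphic entries (0 or n) are ignored. Used by the coalescent null
    and by the simulators, where n is constant across sites.
    """
    counts = np.asarray(counts)
    seg = counts[(counts > 0) & (counts < n)]
    S = int(seg.size)
    if S == 0:
        return 0, 0.0, 0.0, float("nan")
    p = seg / n
    pi_total = float(np.sum(2.0 * p * (1.0 - p)) * n / (n - 1.0))
    a1 = harmonic(n)
    return S, pi_total, S / a1, tajima_d(pi_total, S, n)


# ---------------------------------------------------------------------------
# Gene-level records
# ---------------------------------------------------------------------------

def gene_diversity(
    gm: GenotypeMatrix,
    frag: GeneFragment,
    eff: SiteEffect,
    cm: ClusterMap,
    cluster: str,
    site_class: str,
    l_class_method: str = "nei_gojobori",
    n_summary: str = "median",
) -> DiversityRecord:
    """Diversity record for one (gene, cluster, site class).

    S counts sites segregating *within the cluster*; pi sums each site's own-n
    unbiased heterozygosity; theta_w = S / (a1(n) L_class); D follows Tajima
    (1989) with constants at the summary chromosome count n (median across
    the fragment's class sites by default; alternatives "min", "mean").
    """
    samples = cm.samples_of(cluster)
    if len(samples) < 2:
        raise UndefinedStatistic(f"cluster {cluster} has < 2 samples")
    sub = gm.take_samples(samples)
    keys = sub.site_keys()
    idx = [
        j
        for j, key in enumerate(keys)
        if key[0] == frag.transcript_id and eff.effect.get(key) == site_class
    ]
    L_class = _class_length(frag, site_class, l_class_method)
    if L_class <= 0:
        return DiversityRecord(
            frag.gene_name, cluster, site_class, 0, 0, float("nan"), float("nan"),
            float("nan"), 0.0,
        )
    if not idx:
        n0 = 2 * len(samples)
        return DiversityRecord(
            frag.gene_name, cluster, site_class, 0, n0, 0.0, 0.0, float("nan"), L_class
        )
    dos = sub.dosage[:, idx]
    called = dos != MISSING
    n_per_site = 2 * called.sum(axis=0)
    alt = np.where(called, dos, 0).sum(axis=0)
    usable = n_per_site >= 2
    seg = usable & (alt > 0) & (alt < n_per_site)
    S = int(seg.sum())
    pi_total = float(
        sum(site_pi(int(alt[j]), int(n_per_site[j])) for j in np.flatnonzero(seg))
    )
    ns = n_per_site[usable]
    if ns.size == 0:
        return DiversityRecord(
            frag.gene_name, cluster, site_class, 0, 0, 0.0, 0.0, float("nan"), L_class
        )
    if n_summary == "median":
        n_sum = int(np.median(ns))
    elif n_summary == "min":
        n_sum = int(ns.min())
    elif n_summary == "mean":
        n_sum = int(round(float(ns.mean())))
    else:
        raise ValueError(f"unknown n_summary {n_summary!r}")
    theta_total = S / harmonic(n_sum) if n_sum >= 2 and S > 0 else 0.0
    d = tajima_d(pi_total, S, n_sum)
    return DiversityRecord(
        gene=frag.gene_name,
        cluster=cluster,
        site_class=site_class,
        S=S,
        n_chrom=n_sum,
        pi=pi_total / L_class,
        theta_w=theta_total / L_class,
        d=d,
        L_class=L_class,
        pi_total=pi_total,
    )


def _class_length(frag: GeneFragment, site_class: str, method: str) -> float:
    if method == "nei_gojobori":
        syn, nonsyn = nei_gojobori_site_counts(frag)
        return syn if site_class == "syn" else nonsyn
    if method == "fraction":
        # crude 1/4 of coding positions synonymous, 3/4 nonsynonymous
        return frag.covered_len * (0.25 if site_class == "syn" else 0.75)
    raise ValueError(f"unknown l_class_method {method!r}")


def diversity_table(
    gm: GenotypeMatrix,
    frags: list[GeneFragment],
    eff: SiteEffect,
    cm: ClusterMap,
    **kwargs,
) -> pd.DataFrame:
    """Long-format table of DiversityRecord over gene x cluster x class."""
    rows = []
    for frag in frags:
        for cluster in cm.clusters:
            for sc in SITE_CLASSES:
                rec = gene_diversity(gm, frag, eff, cm, cluster, sc, **kwargs)
                rows.append(rec.__dict__)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Cluster summaries and paired comparisons
# ---------------------------------------------------------------------------

def summarize_clusters(records: pd.DataFrame) -> pd.DataFrame:
    """Per (cluster, site_class): mean/SD of D and pi over genes with defined
    values, plus the fraction of genes with D > 1, D < -1 and in between."""
    rows = []
    for (cluster, sc), grp in records.groupby(["cluster", "site_class"]):
        d = grp["d"].dropna()
        pi = grp.loc[grp["pi"].notna(), "pi"]
        n_def = len(d)
        rows.append(
            {
                "cluster": cluster,
                "site_class": sc,
                "n_genes": len(grp),
                "n_defined_d": n_def,
                "mean_d": d.mean() if n_def else float("nan"),
                "sd_d": d.std(ddof=1) if n_def > 1 else float("nan"),
                "mean_pi": pi.mean() if len(pi) else float("nan"),
                "sd_pi": pi.std(ddof=1) if len(pi) > 1 else float("nan"),
                "frac_d_gt1": float((d > 1).mean()) if n_def else float("nan"),
                "frac_d_lt_m1": float((d < -1).mean()) if n_def else float("nan"),
                "frac_d_mid": float(((d >= -1) & (d <= 1)).mean()) if n_def else float("nan"),
            }
        )
    return pd.DataFrame(rows)


def paired_cluster_test(
    records_a: pd.DataFrame, records_b: pd.DataFrame, value: str = "pi"
) -> tuple[float, float]:
    """Wilcoxon matched-pair (signed-rank) test on per-gene paired values.

    Pairs are matched by gene; zero differences are dropped; two-sided p is
    exact for <= 25 non-zero pairs, else a normal approximation with
    continuity correction.
    """
    a = records_a.set_index("gene")[value]
    b = records_b.set_index("gene")[value]
    genes = a.index.intersection(b.index)
    x = a.loc[genes].to_numpy(dtype=float)
    y = b.loc[genes].to_numpy(dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    diffs = x[ok] - y[ok]
    nz = diffs[diffs != 0]
    if nz.size == 0:
        raise UndefinedStatistic("all paired differences are zero")
    method = "exact" if nz.size <= 25 else "approx"
    res = stats.wilcoxon(
        nz, zero_method="wilcox", correction=(method == "approx"),
        alternative="two-sided", method=method,
    )
    return float(res.statistic), float(res.pvalue)
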