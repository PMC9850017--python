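"""Locus-level local-adaptation scans.

Two complementary scans:

* **FLK** — extends the Lewontin–Krakauer test by comparing per-population
  allele frequencies against the drift expectation under a population tree.
  The tree is a neighbour-joining tree on Reynolds' coancestry distances
  estimated from neutral multi-allelic (microsatellite) loci; the kinship
  matrix F holds root-to-MRCA shared branch lengths. Significance comes from
  a simulated neutral null, splined over total heterozygosity H_T, at the
  0.995 quantile. Because a three-population tree cannot be rooted without an
  external outgroup, the scan is run in rotation: each population serves once
  as outgroup while the other two are tested.

* **PCA/Mahalanobis** — pcadapt-style: per-SNP z-scores from the regression
  of genotypes on the K leading principal components, robustified into
  Mahalanobis distances, corrected by a genomic inflation factor, chi-squared
  p-values and Benjamini–Hochberg FDR control.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import PchipInterpolator
from skbio import DistanceMatrix
from skbio.tree import nj

from .datatypes import MISSING, ClusterMap, GenotypeMatrix, UndefinedStatistic

# ---------------------------------------------------------------------------
# Microsatellites and Reynolds distance
# ---------------------------------------------------------------------------


def read_microsat_table(path) -> pd.DataFrame:
    """Microsatellite genotypes: TSV with sample, locus, allele1, allele2."""
    df = pd.read_csv(path, sep="\t")
    need = {"sample", "locus", "allele1", "allele2"}
    if not need <= set(df.columns):
        raise ValueError(f"microsat table must have columns {sorted(need)}")
    return df


def _allele_freqs(ms: pd.DataFrame, samples: list[str]) -> dict[str, tuple[dict, int]]:
    """Per locus: ({allele: frequency}, n_individuals) within the sample set."""
    sub = ms[ms["sample"].isin(samples)]
    out = {}
    for locus, grp in sub.groupby("locus"):
        alleles = pd.concat([grp["allele1"], grp["allele2"]])
        n = len(grp)
        freqs = (alleles.value_counts() / (2 * n)).to_dict()
        out[locus] = (freqs, n)
    return out


def reynolds_distance(ms: pd.DataFrame, cm: ClusterMap, pop_a: str, pop_b: str) -> float:
    """Reynolds/Weir–Cockerham coancestry distance between two populations.

    Method-of-moments estimator, ratio of sums over loci::

        a_l = (1/2) sum_u (p1u - p2u)^2 - h1/(4 n1) - h2/(4 n2)
        b_l = (h1 + h2) / 2
        theta = sum_l a_l / sum_l (a_l + b_l)

    with ``h_i = 2 n_i (1 - sum p_iu^2) / (2 n_i - 1)`` the unbiased expected
    heterozygosity and ``n_i`` the diploid sample size at the locus. The
    estimator is linear in drift time (expected value is the mean of the two
    populations' inbreeding coefficients since their common ancestor).
    Loci monomorphic in both populations contribute nothing and are dropped.
    """
    fa = _allele_freqs(ms, cm.samples_of(pop_a))
    fb = _allele_freqs(ms, cm.samples_of(pop_b))
    shared = sorted(set(fa) & set(fb))
    if not shared:
        raise ValueError(f"populations {pop_a},{pop_b} share no genotyped locus")
    num = den = 0.0
    used = 0
    for locus in shared:
        p1, n1 = fa[locus]
        p2, n2 = fb[locus]
        alleles = set(p1) | set(p2)
        if len(alleles) < 2:
            continue  # monomorphic everywhere: no information
        sum_sq = sum((p1.get(u, 0.0) - p2.get(u, 0.0)) ** 2 for u in alleles)
        h1 = 2 * n1 * (1 - sum(v * v for v in p1.values())) / (2 * n1 - 1)
        h2 = 2 * n2 * (1 - sum(v * v for v in p2.values())) / (2 * n2 - 1)
        num += 0.5 * sum_sq - h1 / (4 * n1) - h2 / (4 * n2)
        den += 0.5 * sum_sq - h1 / (4 * n1) - h2 / (4 * n2) + 0.5 * (h1 + h2)
        used += 1
    if used == 0 or den <= 0:
        raise UndefinedStatistic(
            f"no informative loci for Reynolds distance {pop_a} vs {pop_b}"
        )
    return max(0.0, num / den)


def reynolds_matrix(ms: pd.DataFrame, cm: ClusterMap) -> pd.DataFrame:
    pops = cm.clusters
    d = pd.DataFrame(0.0, index=pops, columns=pops)
    for i, a in enumerate(pops):
        for b in pops[i + 1 :]:
            v = reynolds_distance(ms, cm, a, b)
            d.loc[a, b] = d.loc[b, a] = v
    return d


# ---------------------------------------------------------------------------
# Population tree and kinship
# ---------------------------------------------------------------------------


@dataclass
class KinshipF:
    """Population co-ancestry matrix from a rooted NJ tree.

    ``F[i, j]`` is the branch length shared by the root-to-tip paths of
    populations i and j (root = the outgroup's attachment point); the
    diagonal is the root-to-tip drift distance. The outgroup itself is
    excluded from the tested set.
    """

    populations: list[str]
    F: np.ndarray
    outgroup: str
    newick: str = ""


def build_pop_tree(distances: pd.DataFrame, outgroup: str) -> KinshipF:
    """Neighbour-joining tree rooted on the outgroup's pendant edge.

    F is read off patristic distances: with root placed at the point where
    the outgroup's edge attaches,
    ``F_ij = (d(o,i) + d(o,j) - d(i,j)) / 2 - pendant(o)``.
    Negative NJ branch contributions are clamped to zero.
    """
    pops = list(distances.index)
    if len(pops) < 3:
        raise ValueError("need >= 3 populations to build an NJ tree")
    if outgroup not in pops:
        raise ValueError(f"outgroup {outgroup!r} not among populations")
    dm = DistanceMatrix(distances.to_numpy(dtype=float), ids=pops)
    tree = nj(dm)
    tips = {t.name: t for t in tree.tips()}
    pend_o = max(0.0, float(tips[outgroup].length or 0.0))
    td = tree.tip_tip_distances(endpoints=pops)
    d = pd.DataFrame(td.data, index=list(td.ids), columns=list(td.ids))
    tested = [p for p in pops if p != outgroup]
    k = len(tested)
    F = np.zeros((k, k))
    for i, a in enumerate(tested):
        for j, b in enumerate(tested):
            if i == j:
                F[i, i] = d.loc[outgroup, a] - pend_o
            else:
                F[i, j] = (d.loc[outgroup, a] + d.loc[outgroup, b] - d.loc[a, b]) / 2 - pend_o
    F = np.maximum(F, 0.0)
    F = (F + F.T) / 2
    return KinshipF(populations=tested, F=F, outgroup=outgroup,
                    newick=str(tree).strip())


# ---------------------------------------------------------------------------
# FLK statistic and null
# ---------------------------------------------------------------------------


def flk_statistic(
    p: np.ndarray,
    kin: KinshipF,
    weights: np.ndarray | None = None,
    p0_method: str = "mean",
) -> float:
    """FLK test statistic T for one SNP.

    ``T = (p - p0 1)' V^{-1} (p - p0 1)`` with ``V = F p0 (1 - p0)``. The
    ancestral frequency p0 is the weighted plug-in mean by default, or the
    GLS estimate ``(1'F^{-1}p) / (1'F^{-1}1)``. Under neutrality T is
    approximately chi-squared with (n_pops - 1) degrees of freedom.
    """
    p = np.asarray(p, dtype=float)
    F = kin.F
    if p.shape != (F.shape[0],):
        raise ValueError("frequency vector length must match tested populations")
    Finv = np.linalg.inv(F)
    if p0_method == "gls":
        one = np.ones(len(p))
        p0 = float(one @ Finv @ p / (one @ Finv @ one))
    elif p0_method == "mean":
        w = np.ones(len(p)) if weights is None else np.asarray(weights, dtype=float)
        p0 = float(np.sum(w * p) / np.sum(w))
    else:
        raise ValueError(f"unknown p0_method {p0_method!r}")
    if p0 <= 0.0 or p0 >= 1.0:
        raise UndefinedStatistic("SNP monomorphic across tested populations")
    r = p - p0
    return float(r @ Finv @ r / (p0 * (1.0 - p0)))


def _flk_T_batch(P: np.ndarray, F: np.ndarray, p0: np.ndarray) -> np.ndarray:
    Finv = np.linalg.inv(F)
    R = P - p0[:, None]
    return np.einsum("ri,ij,rj->r", R, Finv, R) / (p0 * (1 - p0))


@dataclass
class FLKNull:
    """Spline-interpolated 0.995 quantile of neutral T as a function of H_T."""

    bin_centers: np.ndarray
    bin_quantiles: np.ndarray
    quantile: float
    reps: int
    seed: int
    df: int
    _spline: PchipInterpolator = field(repr=False, default=None)

    def threshold(self, h_t: np.ndarray | float) -> np.ndarray:
        h = np.clip(np.asarray(h_t, dtype=float), self.bin_centers[0], self.bin_centers[-1])
        return self._spline(h)


def flk_null(
    kin: KinshipF,
    reps: int = 1_000_000,
    seed: int = 0,
    n_bins: int = 20,
    quantile: float = 0.995,
    model: str = "normal",
    wf_pop_size: int = 500,
    n_chrom: np.ndarray | None = None,
) -> FLKNull:
    """Neutral null quantile curve of T over total heterozygosity.

    Ancestral frequencies are drawn stratified over ``n_bins`` equal-width
    H_T bins on (0, 0.5]; each population's frequency diffuses along its
    branch — multivariate normal with covariance ``F p0 (1-p0)`` clipped to
    [0, 1] (``model="normal"``), or discrete Wright–Fisher binomial
    generations matching each branch's drift length (``model="wf"``,
    validation alternative). When per-population chromosome counts
    ``n_chrom`` are given, the finite-sample binomial sampling of each
    population's frequency is simulated on top of the drift, which matters
    when sample sizes are small relative to the drift depth. Per-bin
    empirical ``quantile`` values are joined by a monotone
    (shape-preserving) cubic spline.
    """
    if reps < n_bins * 100:
        raise ValueError("too few replicates for stable per-bin quantiles")
    rng = np.random.default_rng(seed)
    F = kin.F
    k = F.shape[0]
    per_bin = reps // n_bins
    edges = np.linspace(0.0, 0.5, n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    qs = np.empty(n_bins)
    L = np.linalg.cholesky(F + 1e-12 * np.eye(k))
    for b in range(n_bins):
        h = rng.uniform(edges[b] + 1e-9, min(edges[b + 1], 0.5 - 1e-9), size=per_bin)
        p0 = (1.0 - np.sqrt(1.0 - 2.0 * h)) / 2.0  # lower root; symmetric in T
        flip = rng.random(per_bin) < 0.5
        p0 = np.where(flip, 1.0 - p0, p0)
        sd = np.sqrt(p0 * (1.0 - p0))
        if model == "normal":
            z = rng.standard_normal((per_bin, k))
            P = p0[:, None] + sd[:, None] * (z @ L.T)
            P = np.clip(P, 0.0, 1.0)
        elif model == "wf":
            P = _wf_diffuse(p0, F, wf_pop_size, rng)
        else:
            raise ValueError(f"unknown null model {model!r}")
        if n_chrom is not None:
            nc = np.asarray(n_chrom, dtype=np.int64)
            P = rng.binomial(nc[None, :], P) / nc[None, :]
        pbar = P.mean(axis=1)
        ok = (pbar > 0) & (pbar < 1)
        T = _flk_T_batch(P[ok], F, pbar[ok])
        if T.size < 100:
            raise UndefinedStatistic(f"bin {b}: fewer than 100 usable replicates")
        qs[b] = np.quantile(T, quantile)
    spline = PchipInterpolator(centers, qs)
    return FLKNull(bin_centers=centers, bin_quantiles=qs, quantile=quantile,
                   reps=reps, seed=seed, df=k - 1, _spline=spline)


def _wf_diffuse(p0: np.ndarray, F: np.ndarray, N: int, rng: np.random.Generator) -> np.ndarray:
    """Independent-branch Wright–Fisher drift to depth F_ii (diploid size N).

    Branch length F_ii is converted to ``t = -2N ln(1 - F_ii)`` binomial
    generations so that the realised variance matches ``F_ii p0 (1 - p0)``.
    Shared internal branches are ignored (valid for star-like F, e.g. the
    two-tested-population rotation design).
    """
    k = F.shape[0]
    P = np.tile(p0[:, None], (1, k))
    for i in range(k):
        t = int(round(-2 * N * np.log(max(1e-12, 1.0 - F[i, i]))))
        x = P[:, i]
        for _ in range(t):
            x = rng.binomial(2 * N, x) / (2 * N)
        P[:, i] = x
    return P


# ---------------------------------------------------------------------------
# Population frequencies and the rotation scan
# ---------------------------------------------------------------------------


def pop_freq_table(gm: GenotypeMatrix, cm: ClusterMap, pops: list[str] | None = None) -> pd.DataFrame:
    """Per-SNP per-population alternate-allele frequencies and H_T.

    H_T = 2 p̄ (1 - p̄) with p̄ the chromosome-count-weighted mean frequency
    over the included populations.
    """
    pops = pops if pops is not None else cm.clusters
    base = gm.sites[["transcript", "pos", "ref", "alt"]].copy()
    tot_alt = np.zeros(gm.n_sites)
    tot_n = np.zeros(gm.n_sites)
    for pop in pops:
        sub = gm.take_samples(cm.samples_of(pop))
        alt, n = sub.allele_counts()
        with np.errstate(invalid="ignore", divide="ignore"):
            base[f"freq_{pop}"] = np.where(n > 0, alt / n, np.nan)
        base[f"n_{pop}"] = n
        tot_alt += alt
        tot_n += n
    with np.errstate(invalid="ignore", divide="ignore"):
        pbar = np.where(tot_n > 0, tot_alt / tot_n, np.nan)
    base["p_mean"] = pbar
    base["h_t"] = 2.0 * pbar * (1.0 - pbar)
    return base


def flk_scan(
    gm: GenotypeMatrix,
    ms: pd.DataFrame,
    cm: ClusterMap,
    reps: int = 1_000_000,
    seed: int = 0,
    quantile: float = 0.995,
    p0_method: str = "mean",
) -> pd.DataFrame:
    """Run FLK in rotation over the populations.

    For each rotation one population is the outgroup; the NJ tree on Reynolds
    distances (all populations) is rooted there and the other populations are
    tested. Returns one row per SNP x run with T, H_T, the interpolated
    threshold and the significance call. SNPs monomorphic across the tested
    pair are skipped.
    """
    pops = cm.clusters
    if len(pops) < 3:
        raise ValueError("rotation scan needs >= 3 populations")
    dist = reynolds_matrix(ms, cm)
    rows = []
    for r, outgroup in enumerate(pops):
        kin = build_pop_tree(dist, outgroup)
        tested = kin.populations
        freqs = pop_freq_table(gm, cm, pops=tested)
        n_med = np.array(
            [max(2, int(np.median(freqs[f"n_{p}"]))) for p in tested]
        )
        null = flk_null(kin, reps=reps, seed=seed + 7919 * r, quantile=quantile,
                        n_chrom=n_med)
        P = freqs[[f"freq_{p}" for p in tested]].to_numpy()
        N = freqs[[f"n_{p}" for p in tested]].to_numpy(dtype=float)
        for i in range(len(freqs)):
            p = P[i]
            if np.any(np.isnan(p)):
                continue
            try:
                t_flk = flk_statistic(p, kin, weights=N[i], p0_method=p0_method)
            except UndefinedStatistic:
                continue
            pbar = float(np.sum(N[i] * p) / np.sum(N[i]))
            h_t = 2 * pbar * (1 - pbar)
            thr = float(null.threshold(h_t))
            rows.append(
                {
                    "transcript": freqs.iloc[i]["transcript"],
                    "pos": int(freqs.iloc[i]["pos"]),
                    "run": f"{tested[0]}-{tested[1] if len(tested) > 1 else ''}|out:{outgroup}",
                    "outgroup": outgroup,
                    "t_flk": t_flk,
                    "h_t": h_t,
                    "threshold": thr,
                    "significant": t_flk > thr,
                }
            )
    return pd.DataFrame(rows)


def flk_outlier_summary(scan: pd.DataFrame) -> pd.DataFrame:
    """Union of per-run outliers without double-counting SNPs."""
    sig = scan[scan["significant"]]
    if sig.empty:
        return pd.DataFrame(columns=["transcript", "pos", "runs"])
    agg = (
        sig.groupby(["transcript", "pos"])["run"]
        .apply(lambda s: ";".join(sorted(s)))
        .reset_index()
        .rename(columns={"run": "runs"})
    )
    return agg


# ---------------------------------------------------------------------------
# PCA / Mahalanobis outlier scan
# ---------------------------------------------------------------------------


@dataclass
class PCAOutlierResult:
    table: pd.DataFrame  # snp, d2, p, q, significant
    K: int
    gif: float
    eigenvalues: np.ndarray


def choose_k_elbow(eigenvalues: np.ndarray) -> int:
    """Largest drop between consecutive eigenvalues (automated scree elbow)."""
    ev = np.asarray(eigenvalues, dtype=float)
    if ev.size < 2:
        return 1
    drops = ev[:-1] - ev[1:]
    return int(np.argmax(drops)) + 1


def pca_outlier_scan(
    gm: GenotypeMatrix,
    K: int | None = None,
    alpha: float = 0.05,
    robust: bool = False,
    min_maf: float = 0.0,
) -> PCAOutlierResult:
    """pcadapt-style PCA/Mahalanobis SNP outlier scan with BH FDR control.

    Genotypes are mean-imputed and scaled by the binomial standard deviation
    sqrt(2 p (1-p)); per-SNP z-scores come from the multiple regression of
    each scaled SNP on the K leading PCs; the Mahalanobis distance of the
    K-vector of z-scores (plain covariance, or MCD when ``robust``) is
    divided by the genomic inflation factor median(d2)/median(chi2_K) and
    converted to chi-squared(K) p-values; q-values are Benjamini–Hochberg.
    """
    X = gm.dosage.astype(float)
    X[gm.dosage == MISSING] = np.nan
    p_hat = np.nanmean(X, axis=0) / 2.0
    keep = (p_hat > min_maf) & (p_hat < 1 - min_maf) & (p_hat > 0) & (p_hat < 1)
    idx = np.flatnonzero(keep)
    X = X[:, idx]
    p_hat = p_hat[idx]
    col_mean = 2.0 * p_hat
    inds = np.where(np.isnan(X))
    X[inds] = col_mean[inds[1]]
    Xs = (X - col_mean) / np.sqrt(2.0 * p_hat * (1.0 - p_hat))
    n = Xs.shape[0]
    U, s, _ = np.linalg.svd(Xs, full_matrices=False)
    eig = (s**2) / max(1, n - 1)
    if K is None:
        K = choose_k_elbow(eig)
    if K >= min(Xs.shape):
        raise ValueError(f"K={K} must be < min(n_samples, n_snps)={min(Xs.shape)}")
    Uk = U[:, :K]
    B = Uk.T @ Xs  # (K, n_snps) regression coefficients (orthonormal design)
    resid = Xs - Uk @ B
    dof = max(1, n - K - 1)
    sigma = np.sqrt(np.sum(resid**2, axis=0) / dof)
    sigma[sigma == 0] = np.inf  # SNP fully explained: zero z rather than inf
    Z = (B / sigma).T  # (n_snps, K)
    if robust:
        from sklearn.covariance import MinCovDet

        mcd = MinCovDet(random_state=0).fit(Z)
        center, cov = mcd.location_, mcd.covariance_
    else:
        center = Z.mean(axis=0)
        cov = np.cov(Z, rowvar=False)
        cov = np.atleast_2d(cov)
    Ci = np.linalg.inv(cov + 1e-12 * np.eye(K))
    R = Z - center
    d2 = np.einsum("ri,ij,rj->r", R, Ci, R)
    gif = float(np.median(d2) / stats.chi2.ppf(0.5, K))
    pvals = stats.chi2.sf(d2 / gif, K)
    qvals = stats.false_discovery_control(pvals, method="bh")
    table = gm.sites.iloc[idx][["transcript", "pos", "ref", "alt"]].reset_index(drop=True)
    table["mahalanobis_d2"] = d2
    table["p"] = pvals
    table["q"] = qvals
    table["significant"] = qvals <= alpha
    return PCAOutlierResult(table=table, K=K, gif=gif, eigenvalues=eig)
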