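"""DAPC-style population structure analysis.

Cluster number is selected by BIC over k-means run on principal components
of the (mean-imputed, centred, scaled) dosage matrix; the number of PCs kept
for the discriminant step is selected by stratified cross-validation of
group-mean assignment success; discriminant axes are linear discriminants on
the retained PCs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.model_selection import StratifiedShuffleSplit

from .datatypes import MISSING, ClusterMap, GenotypeMatrix


@dataclass
class StructureModel:
    n_pcs_retained: int
    k_clusters: int
    bic_curve: pd.Series  # index k, value BIC
    assignments: pd.Series  # index sample id, value inferred cluster int
    discriminant_coords: pd.DataFrame | None = None
    xval_error: pd.Series | None = None


def _scaled_matrix(gm: GenotypeMatrix) -> np.ndarray:
    """Mean-imputed, centred, unit-variance dosage matrix (PCA only —
    imputation is never used for the diversity statistics)."""
    X = gm.dosage.astype(float)
    X[gm.dosage == MISSING] = np.nan
    mean = np.nanmean(X, axis=0)
    inds = np.where(np.isnan(X))
    X[inds] = mean[inds[1]]
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    return (X - mean) / sd


def find_clusters(
    gm: GenotypeMatrix,
    k_max: int = 10,
    seed: int = 0,
    n_pca: int | None = None,
    n_restarts: int = 10,
) -> tuple[pd.Series, pd.Series]:
    """BIC-over-k-means cluster-number selection on principal components.

    ``BIC(k) = n ln(WSS_k / n) + k ln(n)`` with WSS the within-cluster sum of
    squares in PC space. Returns (bic_curve, assignments at the lowest-BIC k;
    ties broken toward smaller k).
    """
    if k_max >= gm.n_samples:
        raise ValueError("k_max must be < number of samples")
    if k_max < 2:
        raise ValueError("k_max must be >= 2")
    X = _scaled_matrix(gm)
    n = X.shape[0]
    n_comp = min(n - 1, X.shape[1], n_pca or max(1, n - 1))
    pcs = PCA(n_components=n_comp, random_state=seed).fit_transform(X)
    bics = {}
    labels = {}
    for k in range(1, k_max + 1):
        if k == 1:
            wss = float(((pcs - pcs.mean(axis=0)) ** 2).sum())
            lab = np.zeros(n, dtype=int)
        else:
            km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed).fit(pcs)
            wss = float(km.inertia_)
            lab = km.labels_
        bics[k] = n * np.log(max(wss, 1e-300) / n) + k * np.log(n)
        labels[k] = lab
    bic_curve = pd.Series(bics, name="bic").sort_index()
    best_k = int(bic_curve.idxmin())  # idxmin takes the first (smallest) k on ties
    return bic_curve, pd.Series(labels[best_k], index=gm.sample_ids, name="cluster")


def xval_pcs(
    gm: GenotypeMatrix,
    labels: ClusterMap,
    n_pca_max: int = 80,
    training_fraction: float = 0.8,
    n_rep: int = 100,
    seed: int = 0,
    candidates: list[int] | None = None,
) -> tuple[int, pd.Series]:
    """Cross-validated choice of the PC count for the discriminant step.

    Stratified train/test splits; for each candidate PC count an LDA is fit
    on the training PCs and group-mean assignment success is recorded on the
    held-out samples. Returns the PC count with the highest mean success
    (ties toward fewer PCs) and the per-candidate mean success curve.
    """
    X = _scaled_matrix(gm)
    y = np.array([labels.assignment[s] for s in gm.sample_ids])
    n = X.shape[0]
    max_pcs = int(min(n_pca_max, n - 1, X.shape[1]))
    if candidates is None:
        step = max(1, max_pcs // 8)
        candidates = sorted(set(list(range(step, max_pcs + 1, step)) + [max_pcs]))
    candidates = [c for c in candidates if 1 <= c <= max_pcs]
    pca = PCA(n_components=max_pcs, random_state=seed)
    pcs = pca.fit_transform(X)
    splitter = StratifiedShuffleSplit(
        n_splits=n_rep, train_size=training_fraction, random_state=seed
    )
    success = {c: [] for c in candidates}
    for train, test in splitter.split(pcs, y):
        for c in candidates:
            lda = LinearDiscriminantAnalysis()
            lda.fit(pcs[train, :c], y[train])
            pred = lda.predict(pcs[test, :c])
            # 'groupMean': average per-group success, not pooled accuracy
            per_group = [
                np.mean(pred[y[test] == g] == g) for g in np.unique(y[test])
            ]
            success[c].append(float(np.mean(per_group)))
    curve = pd.Series({c: float(np.mean(v)) for c, v in success.items()}).sort_index()
    best = int(curve.index[np.argmax(curve.to_numpy())])  # first max = fewest PCs
    return best, curve


def dapc_project(
    gm: GenotypeMatrix,
    labels: ClusterMap,
    n_pcs: int,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-sample discriminant coordinates (<= k-1 axes) on retained PCs.

    Axes are sign-fixed so that the first cluster (sorted label order) has a
    non-positive mean on every axis. Singular within-cluster scatter is
    ridge-regularised by sklearn's default solver.
    """
    X = _scaled_matrix(gm)
    y = np.array([labels.assignment[s] for s in gm.sample_ids])
    k = len(np.unique(y))
    if n_pcs < k - 1:
        raise ValueError("n_pcs must be >= n_clusters - 1")
    n_pcs = int(min(n_pcs, X.shape[0] - 1, X.shape[1]))
    pcs = PCA(n_components=n_pcs, random_state=seed).fit_transform(X)
    lda = LinearDiscriminantAnalysis(n_components=k - 1)
    coords = lda.fit_transform(pcs, y)
    first = sorted(np.unique(y))[0]
    for ax in range(coords.shape[1]):
        if coords[y == first, ax].mean() > 0:
            coords[:, ax] *= -1
    out = pd.DataFrame(
        coords,
        index=gm.sample_ids,
        columns=[f"LD{i + 1}" for i in range(coords.shape[1])],
    )
    out["cluster"] = y
    return out
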