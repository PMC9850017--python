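"""FLK machinery (Reynolds distance, NJ kinship, statistic, null) and the
PCA/Mahalanobis scan."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from invadiv import outliers
from invadiv.datatypes import ClusterMap, UndefinedStatistic

from conftest import make_gm


def microsat_table(genos):
    """genos: {sample: {locus: (a1, a2)}} -> long-format table."""
    rows = [
        (s, loc, a, b)
        for s, loci in genos.items()
        for loc, (a, b) in loci.items()
    ]
    return pd.DataFrame(rows, columns=["sample", "locus", "allele1", "allele2"])


def two_pop_ms(p1, p2, n=30, locus="L1"):
    """Biallelic 'microsatellite' with given allele-1 frequencies."""
    genos = {}
    cm = {}
    for pop, p, pref in (("A", p1, "a"), ("B", p2, "b")):
        alleles = [1] * int(round(2 * n * p)) + [2] * (2 * n - int(round(2 * n * p)))
        for i in range(n):
            genos[f"{pref}{i}"] = {locus: (alleles[2 * i], alleles[2 * i + 1])}
            cm[f"{pref}{i}"] = pop
    return microsat_table(genos), ClusterMap(cm)


def test_reynolds_identical_populations_near_zero():
    ms, cm = two_pop_ms(0.5, 0.5, n=50)
    d = outliers.reynolds_distance(ms, cm, "A", "B")
    assert d == pytest.approx(0.0, abs=0.02)


def test_reynolds_symmetry():
    ms, cm = two_pop_ms(0.2, 0.7, n=25)
    assert outliers.reynolds_distance(ms, cm, "A", "B") == pytest.approx(
        outliers.reynolds_distance(ms, cm, "B", "A")
    )


def test_reynolds_hand_computed_single_locus():
    """One biallelic locus, p = 0.2 vs 0.8, n = 30 each."""
    ms, cm = two_pop_ms(0.2, 0.8, n=30)
    n1 = n2 = 30
    p1, p2 = np.array([0.2, 0.8]), np.array([0.8, 0.2])
    h1 = 2 * n1 * (1 - np.sum(p1**2)) / (2 * n1 - 1)
    h2 = 2 * n2 * (1 - np.sum(p2**2)) / (2 * n2 - 1)
    a = 0.5 * np.sum((p1 - p2) ** 2) - h1 / (4 * n1) - h2 / (4 * n2)
    theta = a / (a + 0.5 * (h1 + h2))
    assert outliers.reynolds_distance(ms, cm, "A", "B") == pytest.approx(theta)


def test_reynolds_monomorphic_everywhere_undefined():
    ms, cm = two_pop_ms(1.0, 1.0, n=10)
    with pytest.raises(UndefinedStatistic):
        outliers.reynolds_distance(ms, cm, "A", "B")


def test_build_pop_tree_three_pops_diagonal_F():
    d = pd.DataFrame(
        [[0.0, 0.3, 0.45], [0.3, 0.0, 0.35], [0.45, 0.35, 0.0]],
        index=list("ABC"), columns=list("ABC"),
    )
    kin = outliers.build_pop_tree(d, outgroup="C")
    assert kin.populations == ["A", "B"]
    assert kin.F[0, 1] == pytest.approx(0.0, abs=1e-12)
    # 3-taxon NJ is forced: pendant lengths solve the additive system
    va = (0.3 + 0.45 - 0.35) / 2
    vb = (0.3 + 0.35 - 0.45) / 2
    assert kin.F[0, 0] == pytest.approx(va)
    assert kin.F[1, 1] == pytest.approx(vb)


def test_build_pop_tree_recovers_known_tree():
    """Additive distances from ((A:.1,B:.2):.05,(C:.15,O:.3)): F equals the
    generating branch lengths after rooting at O's attachment."""
    names = ["A", "B", "C", "O"]
    d = pd.DataFrame(0.0, index=names, columns=names)
    dist = {("A", "B"): 0.3, ("A", "C"): 0.3, ("A", "O"): 0.45,
            ("B", "C"): 0.4, ("B", "O"): 0.55, ("C", "O"): 0.45}
    for (x, y), v in dist.items():
        d.loc[x, y] = d.loc[y, x] = v
    kin = outliers.build_pop_tree(d, outgroup="O")
    i = {p: k for k, p in enumerate(kin.populations)}
    assert kin.F[i["A"], i["A"]] == pytest.approx(0.15)
    assert kin.F[i["B"], i["B"]] == pytest.approx(0.25)
    assert kin.F[i["C"], i["C"]] == pytest.approx(0.15)
    assert kin.F[i["A"], i["B"]] == pytest.approx(0.05)
    assert kin.F[i["A"], i["C"]] == pytest.approx(0.0, abs=1e-12)
    # permuting the input leaves F unchanged up to relabeling
    perm = ["C", "O", "A", "B"]
    kin2 = outliers.build_pop_tree(d.loc[perm, perm], outgroup="O")
    j = {p: k for k, p in enumerate(kin2.populations)}
    for x in "ABC":
        for y in "ABC":
            assert kin2.F[j[x], j[y]] == pytest.approx(kin.F[i[x], i[y]], abs=1e-12)


def test_flk_statistic_zero_when_no_differentiation():
    kin = outliers.KinshipF(["A", "B"], np.diag([0.1, 0.2]), "C")
    assert outliers.flk_statistic(np.array([0.4, 0.4]), kin) == pytest.approx(0.0)


def test_flk_two_pop_closed_form():
    f = 0.07
    kin = outliers.KinshipF(["A", "B"], np.diag([f, f]), "C")
    rng = np.random.default_rng(2)
    for _ in range(200):
        p = rng.uniform(0.05, 0.95, 2)
        pbar = p.mean()
        expected = (p[0] - p[1]) ** 2 / (2 * f * pbar * (1 - pbar))
        assert outliers.flk_statistic(p, kin) == pytest.approx(expected, abs=1e-10)


def test_flk_matches_dense_gls_oracle():
    """General-F statistic equals brute-force dense linear algebra."""
    rng = np.random.default_rng(4)
    n_checked = 0
    while n_checked < 200:
        A = rng.normal(size=(3, 3))
        F = A @ A.T + 0.05 * np.eye(3)
        kin = outliers.KinshipF(["A", "B", "C"], F, "O")
        p = rng.uniform(0.1, 0.9, 3)
        Finv = np.linalg.inv(F)
        one = np.ones(3)
        p0 = one @ Finv @ p / (one @ Finv @ one)
        if not 0 < p0 < 1:
            continue  # such sites are excluded by contract
        T = outliers.flk_statistic(p, kin, p0_method="gls")
        r = p - p0
        expected = r @ Finv @ r / (p0 * (1 - p0))
        assert T == pytest.approx(expected, abs=1e-10)
        n_checked += 1


def test_flk_ref_alt_relabel_invariance():
    kin = outliers.KinshipF(["A", "B"], np.diag([0.05, 0.12]), "C")
    p = np.array([0.3, 0.6])
    assert outliers.flk_statistic(p, kin) == pytest.approx(
        outliers.flk_statistic(1 - p, kin)
    )
    with pytest.raises(UndefinedStatistic):
        outliers.flk_statistic(np.array([0.0, 0.0]), kin)


def test_flk_null_deterministic_and_chi2_limit():
    kin = outliers.KinshipF(["A", "B"], np.diag([0.002, 0.002]), "C")
    a = outliers.flk_null(kin, reps=60000, seed=5)
    b = outliers.flk_null(kin, reps=60000, seed=5)
    np.testing.assert_array_equal(a.bin_quantiles, b.bin_quantiles)
    # with tiny drift T ~ chi2(1); 0.995 quantile ~ 7.88 at intermediate H_T
    mid = a.bin_quantiles[10:18]
    assert np.allclose(mid, stats.chi2.ppf(0.995, 1), rtol=0.2)


def test_flk_null_self_calibration():
    f = 0.08
    kin = outliers.KinshipF(["A", "B"], np.diag([f, f]), "C")
    null = outliers.flk_null(kin, reps=100000, seed=1)
    rng = np.random.default_rng(77)
    n = 40000
    p0 = rng.uniform(0.03, 0.97, n)
    sd = np.sqrt(p0 * (1 - p0) * f)
    P = np.clip(p0[:, None] + sd[:, None] * rng.standard_normal((n, 2)), 0, 1)
    pbar = P.mean(axis=1)
    ok = (pbar > 0) & (pbar < 1)
    T = outliers._flk_T_batch(P[ok], kin.F, pbar[ok])
    ht = 2 * pbar[ok] * (1 - pbar[ok])
    rej = float(np.mean(T > null.threshold(ht)))
    assert 0.002 < rej < 0.009


def test_flk_scan_recovers_planted_shifted_snp(small_sim):
    """A SNP with a strongly shifted frequency in one population is flagged
    in the runs testing that population."""
    rng = np.random.default_rng(8)
    n_ind = 30
    n_snp = 60
    dos = np.zeros((3 * n_ind, n_snp), dtype=np.int8)
    f_drift = 0.03
    for j in range(n_snp):
        p0 = rng.uniform(0.2, 0.8)
        for k in range(3):
            p = np.clip(rng.normal(p0, np.sqrt(f_drift * p0 * (1 - p0))), 0.02, 0.98)
            if j == 0 and k == 0:
                p = 0.95  # planted local adaptation in population A
            if j == 0 and k > 0:
                p = 0.1
            dos[k * n_ind : (k + 1) * n_ind, j] = rng.binomial(2, p, size=n_ind)
    gm = make_gm(dos, positions=list(range(1, n_snp + 1)))
    cm = ClusterMap(
        {s: "ABC"[i // n_ind] for i, s in enumerate(gm.sample_ids)}
    )
    ms = _drifted_microsats(rng, gm.sample_ids, cm, f_drift)
    scan = outliers.flk_scan(gm, ms, cm, reps=60000, seed=3)
    planted = scan[(scan["pos"] == 1) & (scan["outgroup"] != "A")]
    assert planted["significant"].all()
    neutral = scan[scan["pos"] != 1]
    assert neutral["significant"].mean() < 0.1


def _drifted_microsats(rng, sample_ids, cm, f):
    """Multi-allelic loci whose spectra drift by ~f between populations."""
    genos = {s: {} for s in sample_ids}
    for loc in range(8):
        anc = rng.integers(95, 106, size=6)
        w = rng.dirichlet(np.ones(6))
        # Balding-Nichols drift: Dirichlet(w (1-f)/f) has Var = f w (1-w)
        pop_w = {pop: rng.dirichlet(w * (1 - f) / f) for pop in cm.clusters}
        for s in sample_ids:
            a, b = rng.choice(anc, size=2, p=pop_w[cm.assignment[s]])
            genos[s][f"L{loc}"] = (int(a), int(b))
    return microsat_table(genos)


def test_bh_step_up_oracle():
    q = stats.false_discovery_control([0.01, 0.02, 0.5], method="bh")
    assert (q <= 0.05).sum() == 2  # step-up: 0.03, 0.03, 0.5


def test_pca_scan_k1_reduces_to_squared_standardised_z(small_sim):
    gm = small_sim.gm
    res = outliers.pca_outlier_scan(gm, K=1)
    d2 = res.table["mahalanobis_d2"].to_numpy()
    assert (d2 >= 0).all()
    # independent 1-D identity: d2 = ((z - mean) / sd)^2 recomputed directly
    from invadiv.datatypes import MISSING

    X = gm.dosage.astype(float)
    X[gm.dosage == MISSING] = np.nan
    p = np.nanmean(X, axis=0) / 2
    keep = (p > 0) & (p < 1)
    X = X[:, keep]
    p = p[keep]
    mu = 2 * p
    inds = np.where(np.isnan(X))
    X[inds] = mu[inds[1]]
    Xs = (X - mu) / np.sqrt(2 * p * (1 - p))
    U, s, _ = np.linalg.svd(Xs, full_matrices=False)
    b = U[:, :1].T @ Xs
    resid = Xs - U[:, :1] @ b
    sig = np.sqrt((resid**2).sum(axis=0) / (Xs.shape[0] - 2))
    z = (b / sig).ravel()
    expected = ((z - z.mean()) / np.std(z, ddof=1)) ** 2
    np.testing.assert_allclose(d2, expected, rtol=1e-6)


def test_pca_scan_errors_on_huge_k(small_sim):
    with pytest.raises(ValueError):
        outliers.pca_outlier_scan(small_sim.gm, K=10_000)


def test_pca_scan_controls_fdr_on_exchangeable_data():
    """No structure, exchangeable samples: few/no discoveries at q <= 0.05."""
    rng = np.random.default_rng(12)
    fps = []
    for rep in range(5):
        p = rng.uniform(0.1, 0.9, size=300)
        dos = rng.binomial(2, p, size=(60, 300)).astype(np.int8)
        gm = make_gm(dos, positions=list(range(1, 301)))
        res = outliers.pca_outlier_scan(gm, K=2)
        fps.append(int(res.table["significant"].sum()))
    assert np.mean(fps) <= 0.05 * 300
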