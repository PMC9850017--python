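"""The invasion simulator: determinism, conservation, demography signatures
and planted-selection properties."""

import numpy as np
import pytest

from invadiv import synthdata, variant_io
from invadiv.datatypes import MISSING
from invadiv.diversity import sfs_statistics
from invadiv.neutral_null import NullCache


def test_fixed_seed_gives_byte_identical_vcf(tmp_path):
    cfg = synthdata.ScenarioConfig(seed=42, n_genes=8, n_microsat=2)
    a = synthdata.simulate_dataset(cfg)
    b = synthdata.simulate_dataset(synthdata.ScenarioConfig(seed=42, n_genes=8,
                                                            n_microsat=2))
    pa = synthdata.write_outputs(a, tmp_path / "a")
    pb = synthdata.write_outputs(b, tmp_path / "b")
    assert pa["vcf"].read_bytes() == pb["vcf"].read_bytes()
    assert pa["truth"].read_text() == pb["truth"].read_text()
    c = synthdata.simulate_dataset(synthdata.ScenarioConfig(seed=43, n_genes=8,
                                                            n_microsat=2))
    assert not np.array_equal(c.gm.dosage, a.gm.dosage) or c.gm.n_sites != a.gm.n_sites


def test_config_echo_sample_sizes(small_sim):
    counts = small_sim.cluster_map.counts()
    assert counts == {"native": 27, "admixed": 30, "isolated": 30}
    assert small_sim.gm.n_samples == 87


def test_emitted_counts_survive_writer_round_trip(small_sim, tmp_path):
    """Per-site allele counts in the written VCF equal the simulator state."""
    paths = synthdata.write_outputs(small_sim, tmp_path)
    back = variant_io.read_vcf(paths["vcf"])
    alt_a, n_a = small_sim.gm.allele_counts()
    alt_b, n_b = back.allele_counts()
    np.testing.assert_array_equal(alt_a, alt_b)
    np.testing.assert_array_equal(n_a, n_b)


def test_every_snp_traceable_to_gene_and_regime(small_sim):
    genes = small_sim.truth["genes"]
    by_tx = {f.transcript_id: f.gene_name for f in small_sim.fragments}
    for rec in small_sim.truth["snps"]:
        assert rec["gene"] == by_tx[rec["transcript"]]
        assert genes[rec["gene"]]["regime"] in {"neutral", "overdominant", "sweep"}
    assert len(small_sim.truth["snps"]) == small_sim.gm.n_sites


def test_neutral_stable_population_mean_d_near_neutral_expectation():
    """Native-cluster mean D over all-neutral genes sits within Monte-Carlo
    error of the coalescent-null expectation at matched (n, S)."""
    cfg = synthdata.ScenarioConfig(seed=77, n_genes=60, frac_overdominant=0.0,
                                   frac_sweep=0.0, n_microsat=0)
    out = synthdata.simulate_dataset(cfg)
    gm = out.gm.take_samples(out.cluster_map.samples_of("native"))
    cache = NullCache(reps=2000, seed=1)
    obs, null_means = [], []
    for f in out.fragments:
        idx = np.flatnonzero((gm.sites["transcript"] == f.transcript_id).values)
        if idx.size == 0:
            continue
        dos = gm.dosage[:, idx]
        called = dos != MISSING
        alt = np.where(called, dos, 0).sum(axis=0)
        n = 2 * gm.n_samples
        _, _, _, d = sfs_statistics(alt, n)
        if np.isnan(d):
            continue
        S = int(((alt > 0) & (alt < n)).sum())
        obs.append(d)
        null_means.append(cache.get(n, S).values.mean())
    obs = np.array(obs)
    se = obs.std(ddof=1) / np.sqrt(len(obs))
    assert abs(obs.mean() - np.mean(null_means)) < 3 * se


def test_bottleneck_cluster_higher_d_lower_pi(small_sim):
    """The isolated severely bottlenecked cluster shows the contraction
    signature relative to the stable native cluster."""
    stats = {}
    for pop in ("native", "isolated"):
        gm = small_sim.gm.take_samples(small_sim.cluster_map.samples_of(pop))
        ds, pis = [], []
        for tx in gm.sites["transcript"].unique():
            idx = np.flatnonzero((gm.sites["transcript"] == tx).values)
            dos = gm.dosage[:, idx]
            alt = np.where(dos != MISSING, dos, 0).sum(axis=0)
            _, pi, _, d = sfs_statistics(alt, 2 * gm.n_samples)
            pis.append(pi)
            if not np.isnan(d):
                ds.append(d)
        stats[pop] = (np.mean(ds), np.mean(pis))
    assert stats["isolated"][0] > stats["native"][0]  # mean D higher
    assert stats["isolated"][1] < stats["native"][1]  # mean pi lower


def test_overdominant_focal_sites_stay_intermediate(default_sim):
    """Wright's symmetric overdominance equilibrium holds the focal allele
    near 0.5; planted focal sites have elevated pooled heterozygosity."""
    focal_keys = {(r["transcript"], r["pos"])
                  for r in default_sim.truth["snps"] if r["focal"]}
    over_genes = {g for g, v in default_sim.truth["genes"].items()
                  if v["regime"] == "overdominant"}
    gm = default_sim.gm
    alt, n = gm.allele_counts()
    freqs = alt / n
    focal_freqs, other = [], []
    for j, key in enumerate(gm.site_keys()):
        if key in focal_keys and key[0].removeprefix("t_") in over_genes:
            focal_freqs.append(freqs[j])
        else:
            other.append(freqs[j])
    assert len(focal_freqs) >= 4  # most planted genes retain the polymorphism
    focal_het = [2 * p * (1 - p) for p in focal_freqs]
    other_het = [2 * p * (1 - p) for p in other]
    assert np.mean(focal_het) > np.mean(other_het)
    assert np.median(np.abs(np.array(focal_freqs) - 0.5)) < 0.25


def test_default_scenario_meets_informativeness_targets(default_sim):
    """Filtering keeps >= 90 fragments and the retained-fragment SNP-count
    median falls in the band around the targeted value of ~4-5."""
    gm, frags = default_sim.gm, default_sim.fragments
    gm = variant_io.mask_and_filter_sites(gm, 80, 10, 0.15)
    gm, frags = variant_io.drop_duplicate_fragments(gm, frags, 0.9)
    gm, frags = variant_io.select_informative_fragments(gm, frags, 150, 3)
    assert len(frags) >= 90
    counts = gm.sites["transcript"].value_counts()
    med = np.median([counts[f.transcript_id] for f in frags])
    assert 3 <= med <= 6


def test_microsats_not_associated_with_selected_genes(default_sim):
    """Neutral microsatellites carry no per-locus association with the
    planted selected genes (permutation check)."""
    rng = np.random.default_rng(0)
    ms = default_sim.microsats
    # within one cluster only, so population structure cannot induce
    # correlation between unlinked loci
    native = default_sim.cluster_map.samples_of("native")
    gm = default_sim.gm.take_samples(native)
    focal = [(r["transcript"], r["pos"]) for r in default_sim.truth["snps"]
             if r["focal"]]
    assert focal, "the default scenario retains at least one focal site"
    key = focal[0]
    j = gm.site_keys().index(key)
    dos = gm.dosage[:, j].astype(float)
    dos[dos == MISSING] = np.nan
    n_exceed = 0
    loci = ms["locus"].unique()
    for locus in loci:
        sub = ms[ms["locus"] == locus].set_index("sample")
        sizes = (sub["allele1"] + sub["allele2"]).reindex(gm.sample_ids).to_numpy(float)
        ok = ~(np.isnan(sizes) | np.isnan(dos))
        r_obs = abs(np.corrcoef(sizes[ok], dos[ok])[0, 1])
        perm = [abs(np.corrcoef(rng.permutation(sizes[ok]), dos[ok])[0, 1])
                for _ in range(200)]
        if r_obs > np.quantile(perm, 0.95):
            n_exceed += 1
    # binomial(9, 0.05): >= 4 exceedances would be wildly improbable
    assert n_exceed <= 3
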