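"""Synthetic three-cluster invasion datasets with planted selection.

The generator emulates the statistical structure the analysis assumes: a
stable native population, an admixed-then-bottlenecked-then-expanding
invasive cluster, and a severely bottlenecked isolated invasive cluster;
~110 short coding gene fragments with a handful of SNPs each; a mix of
neutral genes and genes carrying one focal site under overdominant or
directional (sweep) selection; and a small panel of neutral multi-allelic
microsatellite loci evolving under strict stepwise mutation on the same
demography. A truth table records every planted regime for recovery testing.

Model
-----
Forward-time diploid Wright–Fisher per gene, no recombination within a
fragment and free recombination between fragments (each gene, and each
microsatellite locus, is simulated on its own independent pedigree). The
ancestral population starts at mutation–drift equilibrium, initialised from
a neutral coalescent genealogy. Selection is viability selection on the
diploid genotype at one focal site per non-neutral gene: overdominance has
fitnesses (1-s, 1, 1-s), a sweep is additive (1, 1+s, 1+2s) for the derived
allele. Population sizes are scaled down (N of a few hundred) with
correspondingly interpreted s and mu to keep desk-scale runtimes; see the
methods note.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.Data.CodonTable import standard_dna_table

from .datatypes import ClusterMap, GeneFragment, GenotypeMatrix, MISSING
from .variant_io import write_vcf

_BASES = np.array(["A", "C", "G", "T"])
_NONSTOP_CODONS = sorted(standard_dna_table.forward_table.keys())

NATIVE, ADMIXED, ISOLATED = "native", "admixed", "isolated"


@dataclass
class ScenarioConfig:
    """Study conditions for one synthetic dataset. ``seed`` is mandatory."""

    seed: int
    n_genes: int = 110
    len_log_mean: float = 6.49  # ln 660 bp (median fragment length)
    len_log_sd: float = 0.45
    len_min: int = 167
    len_max: int = 2053
    mu: float = 1.1e-6  # per bp per generation (scaled)
    # demography (generations run forward; sizes are scaled-down diploid N)
    n_ancestral: int = 300
    n_source: int = 150
    t_total: int = 100            # native/source depth
    t_admixed_found: int = 40     # admixed cluster founded at this generation
    admixed_founders: int = 30    # diploids, half from each source
    admixed_bottleneck_gens: int = 10
    n_admixed_final: int = 300    # exponential growth target
    t_isolated_found: int = 55
    isolated_founders: int = 8
    n_isolated: int = 30          # held small and isolated
    # samples drawn at the end
    sample_sizes: dict = field(
        default_factory=lambda: {NATIVE: 27, ADMIXED: 30, ISOLATED: 30}
    )
    # selection plan
    frac_overdominant: float = 0.05
    s_overdominant: float = 0.3
    # age of the balanced polymorphism: expected fixed differences between
    # the two allelic classes = overdominant_div_factor * theta_gene
    overdominant_div_factor: float = 2.0
    frac_sweep: float = 0.02
    s_sweep: float = 0.2
    # microsatellites
    n_microsat: int = 9
    smm_rate: float = 5e-4
    microsat_init_theta: float = 6.0  # ancestral (unscaled-species) diversity
    # emission noise
    p_low_gq: float = 0.03
    p_missing: float = 0.005
    mean_dp: float = 25.0

    def validate(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for name in ("mu", "smm_rate", "frac_overdominant", "frac_sweep"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.frac_overdominant + self.frac_sweep > 1:
            raise ValueError("selection fractions must sum to <= 1")


@dataclass
class SimOutput:
    gm: GenotypeMatrix
    fragments: list[GeneFragment]
    cluster_map: ClusterMap
    microsats: pd.DataFrame
    truth: dict


def default_paper_like_scenario(seed: int = 0) -> ScenarioConfig:
    """Packaged default: 87 samples in 27/30/30 clusters, ~110 genes of
    167–2053 bp, ~5% overdominant and ~2% sweep genes, 9 microsatellites."""
    return ScenarioConfig(seed=seed)


# ---------------------------------------------------------------------------
# Coalescent initialisation of the ancestral population
# ---------------------------------------------------------------------------

def _equilibrium_haplotypes(
    n_hap: int, theta: float, rng: np.random.Generator
) -> np.ndarray:
    """(n_hap, S) 0/1 incidence of a neutral equilibrium sample.

    One Kingman genealogy; Poisson(theta T/2) mutations on branches; each
    mutation's carriers are the leaves below its branch.
    """
    n = n_hap
    times = np.zeros(2 * n - 1)
    parent = np.full(2 * n - 1, -1, dtype=np.int64)
    active = np.arange(n)
    n_active = n
    t = 0.0
    nxt = n
    while n_active > 1:
        k = n_active
        t += rng.exponential(2.0 / (k * (k - 1)))
        i = int(rng.integers(k))
        j = int(rng.integers(k - 1))
        if j >= i:
            j += 1
        a, b = active[i], active[j]
        times[nxt] = t
        parent[a] = nxt
        parent[b] = nxt
        # swap-remove the two merged lineages, append the new one
        hi, lo = max(i, j), min(i, j)
        active[hi] = active[n_active - 1]
        active[lo] = active[n_active - 2]
        active[n_active - 2] = nxt
        n_active -= 1
        nxt += 1
    lengths = np.zeros(2 * n - 1)
    has_par = parent >= 0
    lengths[has_par] = times[parent[has_par]] - times[has_par]
    total = lengths.sum()
    s = int(rng.poisson(theta * total / 2.0)) if total > 0 else 0
    out = np.zeros((n, s), dtype=np.int8)
    if s == 0:
        return out
    branch = rng.choice(2 * n - 1, size=s, p=lengths / total)
    children: dict[int, list[int]] = {}
    for v in range(2 * n - 1):
        if parent[v] >= 0:
            children.setdefault(int(parent[v]), []).append(v)
    for col, v in enumerate(branch):
        stack = [int(v)]
        while stack:
            u = stack.pop()
            if u < n:
                out[u, col] = 1
            else:
                stack.extend(children.get(u, ()))
    return out


def _balanced_ancestral(
    g: "_Gene", n_hap: int, theta: float, cfg: ScenarioConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Ancestral sample for a gene under long-standing overdominance.

    A balanced polymorphism maintained near Wright's symmetric equilibrium
    (p* = 0.5) for much longer than 4N generations behaves like two allelic
    classes with deep coalescence between them: each class carries its own
    private variation (within-class theta = theta/2 at class size N/2) and
    the classes differ at the focal site plus a Poisson number of linked
    fixed differences proportional to the polymorphism's age. All
    class-diagnostic variants therefore segregate near frequency 0.5.
    """
    n_a = n_hap // 2
    n_b = n_hap - n_a
    HA = _equilibrium_haplotypes(n_a, theta / 2.0, rng)
    HB = _equilibrium_haplotypes(n_b, theta / 2.0, rng)
    n_div = int(rng.poisson(cfg.overdominant_div_factor * theta))
    s_a, s_b = HA.shape[1], HB.shape[1]
    S = s_a + s_b + 1 + n_div
    H = np.zeros((n_hap, S), dtype=np.int8)
    H[:n_a, :s_a] = HA
    H[n_a:, s_a : s_a + s_b] = HB
    H[n_a:, s_a + s_b : s_a + s_b + 1 + n_div] = 1  # focal + fixed differences
    pos = rng.choice(g.n_mutable, size=S, replace=False)
    for p in pos:
        g.positions = np.append(g.positions, int(p))
        ref = g.ref_seq[int(p)]
        g.alt_bases.append(str(rng.choice([b for b in "ACGT" if b != ref])))
    g.focal_pos = int(pos[s_a + s_b])
    perm = rng.permutation(n_hap)  # random diploid pairing (HWE)
    return H[perm]


# ---------------------------------------------------------------------------
# Per-gene forward simulation
# ---------------------------------------------------------------------------

class _Gene:
    """Mutable per-gene state: global site registry + per-population
    haplotype matrices aligned to it."""

    def __init__(self, name: str, length: int, regime: str, s_coef: float,
                 cfg: ScenarioConfig, rng: np.random.Generator):
        self.name = name
        self.length = length
        self.regime = regime  # neutral | overdominant | sweep
        self.s = s_coef
        self.mu_gene = cfg.mu * length
        n_codons = length // 3
        codons = rng.choice(len(_NONSTOP_CODONS), size=n_codons)
        seq = "".join(_NONSTOP_CODONS[c] for c in codons)
        seq += "".join(rng.choice(_BASES, size=length - 3 * n_codons))
        self.ref_seq = seq
        # mutations only in complete codons (the ragged tail carries no SNPs)
        self.n_mutable = 3 * (length // 3)
        self.positions = np.zeros(0, dtype=np.int64)  # 0-based
        self.alt_bases: list[str] = []
        self.focal_pos = -1
        self.pops: dict[str, np.ndarray] = {}
        self._free = None  # lazily built free-position pool

    # -- site registry ------------------------------------------------------

    def _new_position(self, rng: np.random.Generator) -> int:
        while True:
            pos = int(rng.integers(self.n_mutable))
            if pos not in set(self.positions.tolist()):
                return pos

    def add_site(self, pos: int, rng: np.random.Generator) -> int:
        ref = self.ref_seq[pos]
        alt = str(rng.choice([b for b in "ACGT" if b != ref]))
        self.positions = np.append(self.positions, pos)
        self.alt_bases.append(alt)
        for p in self.pops:
            self.pops[p] = np.concatenate(
                [self.pops[p], np.zeros((self.pops[p].shape[0], 1), dtype=np.int8)],
                axis=1,
            )
        return len(self.positions) - 1

    def prune(self) -> None:
        """Drop columns globally lost or globally fixed (invisible downstream).
        The focal site is kept while it still segregates anywhere."""
        if len(self.positions) == 0 or not self.pops:
            return
        lost = np.ones(len(self.positions), dtype=bool)
        fixed = np.ones(len(self.positions), dtype=bool)
        for H in self.pops.values():
            c = H.sum(axis=0)
            lost &= c == 0
            fixed &= c == H.shape[0]
        drop = lost | fixed
        if self.focal_pos >= 0:
            focal_idx = np.flatnonzero(self.positions == self.focal_pos)
            if focal_idx.size and fixed[focal_idx[0]]:
                self.regime = "neutral"  # sweep completed; selection over
                self.focal_pos = -1
        keep = ~drop
        if drop.any():
            self.positions = self.positions[keep]
            self.alt_bases = [a for a, k in zip(self.alt_bases, keep) if k]
            for p in self.pops:
                self.pops[p] = self.pops[p][:, keep]

    # -- selection ----------------------------------------------------------

    def _fitness(self, H: np.ndarray) -> np.ndarray | None:
        if self.regime == "neutral" or self.focal_pos < 0:
            return None
        idx = np.flatnonzero(self.positions == self.focal_pos)
        if idx.size == 0:
            return None
        g = H[0::2, idx[0]].astype(np.int64) + H[1::2, idx[0]]
        if self.regime == "overdominant":
            w = np.where(g == 1, 1.0, 1.0 - self.s)
        else:  # sweep, additive
            w = 1.0 + self.s * g
        return w

    # -- one Wright-Fisher generation ---------------------------------------

    def step(self, pop: str, n_new: int, rng: np.random.Generator) -> None:
        H = self.pops[pop]
        n_old = H.shape[0] // 2
        w = self._fitness(H)
        if w is None:
            hap = rng.integers(0, 2 * n_old, size=2 * n_new)
        else:
            parents = rng.choice(n_old, size=2 * n_new, p=w / w.sum())
            hap = 2 * parents + rng.integers(0, 2, size=2 * n_new)
        Hn = H[hap]
        n_mut = rng.poisson(2 * n_new * self.mu_gene)
        if n_mut:
            self.pops[pop] = Hn
            for _ in range(n_mut):
                pos = self._new_position(rng)
                col = self.add_site(pos, rng)
                self.pops[pop][int(rng.integers(2 * n_new)), col] = 1
        else:
            self.pops[pop] = Hn

    def found(self, new_pop: str, source_haps: np.ndarray) -> None:
        self.pops[new_pop] = source_haps.copy()


# ---------------------------------------------------------------------------
# Microsatellites (strict stepwise mutation)
# ---------------------------------------------------------------------------

class _Microsat:
    def __init__(self, name: str, cfg: ScenarioConfig, rng: np.random.Generator,
                 n_hap: int):
        self.name = name
        self.rate = cfg.smm_rate
        steps = _equilibrium_haplotypes(n_hap, cfg.microsat_init_theta, rng)
        signs = rng.choice([-1, 1], size=steps.shape[1])
        self.pops: dict[str, np.ndarray] = {}
        self._anc = 100 + (steps * signs).sum(axis=1).astype(np.int64)

    def init_pop(self, pop: str, alleles: np.ndarray) -> None:
        self.pops[pop] = alleles.copy()

    def step(self, pop: str, n_new: int, rng: np.random.Generator) -> None:
        a = self.pops[pop]
        nxt = a[rng.integers(0, a.size, size=2 * n_new)].copy()
        n_mut = rng.poisson(2 * n_new * self.rate)
        for _ in range(n_mut):
            i = int(rng.integers(nxt.size))
            nxt[i] += int(rng.choice([-1, 1]))
        self.pops[pop] = nxt


# ---------------------------------------------------------------------------
# Scenario driver
# ---------------------------------------------------------------------------

def _admixed_size(cfg: ScenarioConfig, gen: int) -> int:
    """Diploid size of the admixed cluster at generation ``gen``."""
    t0 = cfg.t_admixed_found
    tb = t0 + cfg.admixed_bottleneck_gens
    if gen <= tb:
        return cfg.admixed_founders
    frac = (gen - tb) / max(1, cfg.t_total - tb)
    return int(round(cfg.admixed_founders *
                     (cfg.n_admixed_final / cfg.admixed_founders) ** frac))


def simulate_dataset(cfg: ScenarioConfig) -> SimOutput:
    """Run the full scenario and assemble analysis-ready objects.

    Deterministic under ``cfg.seed`` (byte-identical VCF on re-run).
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    # selection plan
    n_over = int(round(cfg.frac_overdominant * cfg.n_genes))
    n_sweep = int(round(cfg.frac_sweep * cfg.n_genes))
    regimes = (["overdominant"] * n_over + ["sweep"] * n_sweep
               + ["neutral"] * (cfg.n_genes - n_over - n_sweep))
    rng.shuffle(regimes)

    lengths = np.exp(rng.normal(cfg.len_log_mean, cfg.len_log_sd, size=cfg.n_genes))
    lengths = np.clip(np.round(lengths).astype(int), cfg.len_min, cfg.len_max)

    genes: list[_Gene] = []
    truth_genes = {}
    n_hap_anc = 2 * cfg.n_ancestral
    for i in range(cfg.n_genes):
        name = f"G{i + 1:03d}"
        s = (cfg.s_overdominant if regimes[i] == "overdominant"
             else cfg.s_sweep if regimes[i] == "sweep" else 0.0)
        g = _Gene(name, int(lengths[i]), regimes[i], s, cfg, rng)
        # ancestral equilibrium sample
        theta = 4 * cfg.n_ancestral * cfg.mu * g.length
        if regimes[i] == "overdominant":
            H = _balanced_ancestral(g, n_hap_anc, theta, cfg, rng)
        else:
            H = _equilibrium_haplotypes(n_hap_anc, theta, rng)
            pos = rng.choice(g.n_mutable, size=H.shape[1], replace=False)
            for p in pos:
                g.positions = np.append(g.positions, int(p))
                ref = g.ref_seq[int(p)]
                g.alt_bases.append(str(rng.choice([b for b in "ACGT" if b != ref])))
        g.pops[NATIVE] = H.astype(np.int8)
        if regimes[i] == "sweep":
            # plant a standing low-frequency variant the sweep will favour
            fpos = g._new_position(rng)
            col = len(g.positions)
            g.positions = np.append(g.positions, fpos)
            ref = g.ref_seq[fpos]
            g.alt_bases.append(str(rng.choice([b for b in "ACGT" if b != ref])))
            g.pops[NATIVE] = np.concatenate(
                [g.pops[NATIVE], np.zeros((n_hap_anc, 1), dtype=np.int8)], axis=1
            )
            carriers = rng.choice(n_hap_anc, size=max(1, int(round(0.05 * n_hap_anc))),
                                  replace=False)
            g.pops[NATIVE][carriers, col] = 1
            g.focal_pos = fpos
        truth_genes[name] = {
            "regime": regimes[i],
            "s": s,
            "length": int(g.length),
            "focal_pos_1based": (g.focal_pos + 1) if g.focal_pos >= 0 else None,
        }
        genes.append(g)

    microsats = [_Microsat(f"ms{i + 1:02d}", cfg, rng, n_hap_anc)
                 for i in range(cfg.n_microsat)]

    units: list = list(genes) + list(microsats)

    # found the two source pools from the ancestral/native population
    for u in units:
        base = u.pops[NATIVE] if isinstance(u, _Gene) else u._anc
        for src in ("src1", "src2"):
            draw = rng.integers(0, n_hap_anc, size=2 * cfg.n_source)
            if isinstance(u, _Gene):
                u.found(src, base[draw])
            else:
                u.init_pop(src, base[draw])
        if isinstance(u, _Microsat):
            u.init_pop(NATIVE, u._anc)

    pop_size = {NATIVE: cfg.n_ancestral, "src1": cfg.n_source, "src2": cfg.n_source}

    for gen in range(1, cfg.t_total + 1):
        if gen == cfg.t_admixed_found:
            half = cfg.admixed_founders  # haplotypes per source (half diploids each)
            for u in units:
                a = u.pops["src1"]
                b = u.pops["src2"]
                d1 = rng.integers(0, a.shape[0] if a.ndim > 1 else a.size, size=half)
                d2 = rng.integers(0, b.shape[0] if b.ndim > 1 else b.size, size=half)
                founders = (np.concatenate([a[d1], b[d2]], axis=0)
                            if isinstance(u, _Gene)
                            else np.concatenate([a[d1], b[d2]]))
                if isinstance(u, _Gene):
                    u.found(ADMIXED, founders)
                else:
                    u.init_pop(ADMIXED, founders)
            pop_size[ADMIXED] = cfg.admixed_founders
        if gen == cfg.t_isolated_found:
            for u in units:
                a = u.pops["src1"]
                d = rng.integers(0, a.shape[0] if a.ndim > 1 else a.size,
                                 size=2 * cfg.isolated_founders)
                if isinstance(u, _Gene):
                    u.found(ISOLATED, a[d])
                else:
                    u.init_pop(ISOLATED, a[d])
            pop_size[ISOLATED] = cfg.isolated_founders
        if ADMIXED in pop_size:
            pop_size[ADMIXED] = _admixed_size(cfg, gen)
        if ISOLATED in pop_size and gen > cfg.t_isolated_found:
            pop_size[ISOLATED] = cfg.n_isolated
        for u in units:
            for pop, n_new in pop_size.items():
                if pop in u.pops:
                    u.step(pop, n_new, rng)
        if gen % 5 == 0:
            for g in genes:
                g.prune()

    for g in genes:
        g.prune()

    # ----- sample individuals and emit ------------------------------------
    clusters = [NATIVE, ADMIXED, ISOLATED]
    sample_ids, assign = [], {}
    sample_slices: dict[str, np.ndarray] = {}
    for pop in clusters:
        n_s = cfg.sample_sizes[pop]
        ind = rng.choice(pop_size[pop], size=n_s, replace=False)
        sample_slices[pop] = ind
        for i in range(n_s):
            sid = f"{pop[:3].upper()}_{i + 1:02d}"
            sample_ids.append(sid)
            assign[sid] = pop

    site_rows, dosage_cols = [], []
    truth_snps = []
    frags = []
    for g in genes:
        tx = f"t_{g.name}"
        frags.append(GeneFragment(
            gene_name=g.name, transcript_id=tx,
            intervals=[(1, g.length)], frame_offset=0, coding_seq=g.ref_seq,
        ))
        if len(g.positions) == 0:
            continue
        hap_blocks = []
        for pop in clusters:
            ind = sample_slices[pop]
            hap_idx = np.column_stack([2 * ind, 2 * ind + 1]).reshape(-1)
            hap_blocks.append(g.pops[pop][hap_idx])
        haps = np.concatenate(hap_blocks, axis=0)  # (2*total_samples, S)
        dos = haps[0::2].astype(np.int16) + haps[1::2]
        tot = dos.sum(axis=0)
        seg = (tot > 0) & (tot < dos.shape[0] * 2)
        order = np.argsort(g.positions[seg], kind="stable")
        cols = np.flatnonzero(seg)[order]
        for c in cols:
            pos1 = int(g.positions[c]) + 1
            site_rows.append((tx, pos1, g.ref_seq[g.positions[c]], g.alt_bases[c]))
            dosage_cols.append(dos[:, c].astype(np.int8))
            truth_snps.append({
                "transcript": tx, "pos": pos1, "gene": g.name,
                "focal": bool(g.positions[c] == g.focal_pos),
            })

    n_samp = len(sample_ids)
    dosage = (np.stack(dosage_cols, axis=1) if dosage_cols
              else np.zeros((n_samp, 0), dtype=np.int8))
    n_sites = dosage.shape[1]
    gq = np.full((n_samp, n_sites), 99.0, dtype=np.float32)
    low = rng.random((n_samp, n_sites)) < cfg.p_low_gq
    gq[low] = rng.integers(10, 80, size=int(low.sum())).astype(np.float32)
    dp = rng.poisson(cfg.mean_dp, size=(n_samp, n_sites)).astype(np.float32)
    miss = rng.random((n_samp, n_sites)) < cfg.p_missing
    dosage = dosage.copy()
    dosage[miss] = MISSING

    gm = GenotypeMatrix(
        sample_ids=sample_ids,
        sites=pd.DataFrame(site_rows, columns=["transcript", "pos", "ref", "alt"]),
        dosage=dosage, gq=gq, dp=dp,
    )

    ms_rows = []
    for m in microsats:
        for pop in clusters:
            ind = sample_slices[pop]
            a = m.pops[pop]
            for i, d in enumerate(ind):
                sid = f"{pop[:3].upper()}_{i + 1:02d}"
                ms_rows.append((sid, m.name, int(a[2 * d]), int(a[2 * d + 1])))
    ms = pd.DataFrame(ms_rows, columns=["sample", "locus", "allele1", "allele2"])

    truth = {
        "config": asdict(cfg),
        "genes": truth_genes,
        "snps": truth_snps,
        "clusters": {NATIVE: "stable native", ADMIXED: "admixed+bottleneck+growth",
                     ISOLATED: "severe bottleneck, isolated"},
    }
    return SimOutput(gm=gm, fragments=frags, cluster_map=ClusterMap(assign),
                     microsats=ms, truth=truth)


# ---------------------------------------------------------------------------
# File emission
# ---------------------------------------------------------------------------

def write_outputs(out: SimOutput, out_dir: str | Path) -> dict[str, Path]:
    """Write VCF, annotation TSV + FASTA, cluster map, microsats, truth JSON."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": out_dir / "genotypes.vcf",
        "annotation": out_dir / "fragments.tsv",
        "fasta": out_dir / "reference.fasta",
        "clusters": out_dir / "clusters.tsv",
        "microsats": out_dir / "microsats.tsv",
        "truth": out_dir / "truth.json",
    }
    write_vcf(out.gm, paths["vcf"])
    rows = []
    with open(paths["fasta"], "w") as fa:
        for f in out.fragments:
            rows.append((f.gene_name, f.transcript_id, f.intervals[0][0],
                         f.intervals[0][1], f.frame_offset, f.coding_seq))
            fa.write(f">{f.transcript_id}\n")
            for i in range(0, len(f.coding_seq), 60):
                fa.write(f.coding_seq[i:i + 60] + "\n")
    pd.DataFrame(rows, columns=["gene", "transcript", "start", "end",
                                "frame_offset", "coding_seq"]
                 ).to_csv(paths["annotation"], sep="\t", index=False)
    pd.DataFrame(
        [(s, c) for s, c in out.cluster_map.assignment.items()],
        columns=["sample", "cluster"],
    ).to_csv(paths["clusters"], sep="\t", index=False)
    out.microsats.to_csv(paths["microsats"], sep="\t", index=False)
    with open(paths["truth"], "w") as fh:
        json.dump(out.truth, fh, indent=1)
    return paths
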