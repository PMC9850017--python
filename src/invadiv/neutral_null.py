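"""Neutral coalescent null distributions of Tajima's D.

Per-gene significance is assessed ms-style: a standard constant-size
coalescent (no recombination) of n chromosomes is simulated; mutations are
Poisson with mean theta * T_total / 2 (time in units of 4N generations) and
fall on branches proportionally to branch length; Tajima's D is computed for
each replicate; the one-sided empirical p is the tail proportion in the
direction of the observed sign.

theta conditioning follows the observed polymorphism of the gene:
``watterson`` (default; theta = S/a1(n), so the null depends on the gene only
through (n, S)), ``pi``, or ``fixed_S`` (condition on the observed S, ms -s).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datatypes import UndefinedStatistic
from .diversity import harmonic, sfs_statistics


@dataclass
class NullDistribution:
    n_chrom: int
    theta: float
    reps: int
    values: np.ndarray  # sorted ascending, undefined-D replicates dropped
    seed: int
    n_undefined: int = 0


def _coalescent_tree(n: int, rng: np.random.Generator):
    """One Kingman genealogy of n chromosomes.

    Returns (lengths, leaf_counts, total_length): per-branch lengths (in 4N
    units) and the number of sampled leaves below each branch, for the 2n-2
    non-root branches.
    """
    # node ids: 0..n-1 leaves, then internal nodes as they appear
    ks = np.arange(n, 1, -1, dtype=np.float64)
    waits = rng.exponential(2.0 / (ks * (ks - 1)))  # rate k(k-1)/2, 2N units
    node_time = np.concatenate([np.zeros(n), np.cumsum(waits)])
    leaves = np.ones(2 * n - 1, dtype=np.int64)
    parent_time = np.empty(2 * n - 2)
    active = np.arange(n)
    n_active = n
    nxt = n
    for step in range(n - 1):
        k = n_active
        i = int(rng.integers(k))
        j = int(rng.integers(k - 1))
        if j >= i:
            j += 1
        a, b = int(active[i]), int(active[j])
        leaves[nxt] = leaves[a] + leaves[b]
        parent_time[a] = node_time[nxt]
        parent_time[b] = node_time[nxt]
        hi, lo = (i, j) if i > j else (j, i)
        active[hi] = active[n_active - 1]
        active[lo] = active[n_active - 2]
        active[n_active - 2] = nxt
        n_active -= 1
        nxt += 1
    lengths = parent_time - node_time[: 2 * n - 2]
    return lengths, leaves[: 2 * n - 2], float(lengths.sum())


def simulate_neutral_gene(
    n: int, theta: float, rng: np.random.Generator | int, fixed_s: int | None = None
) -> np.ndarray:
    """Derived-allele counts of one neutral constant-size coalescent gene.

    Mutation count ~ Poisson(theta * T_total / 2) placed uniformly on
    branches (or exactly ``fixed_s`` mutations when conditioning on S).
    Coalescent waiting times are exponential with rate k(k-1)/2 in units of
    2N generations; with theta = 4 N mu this pairing gives E[S] = theta a1(n).
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    if fixed_s is None and theta <= 0:
        raise ValueError("theta must be > 0")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    lengths, counts, total = _coalescent_tree(n, rng)
    s = int(rng.poisson(theta * total / 2.0)) if fixed_s is None else int(fixed_s)
    if s == 0:
        return np.zeros(0, dtype=np.int64)
    cdf = np.cumsum(lengths)
    branches = np.searchsorted(cdf, rng.random(s) * total)
    return counts[np.minimum(branches, lengths.size - 1)]


def null_distribution_D(
    n: int,
    theta: float,
    reps: int = 9999,
    seed: int = 0,
    fixed_s: int | None = None,
) -> NullDistribution:
    """Null distribution of Tajima's D from ``reps`` neutral replicates.

    Replicates with undefined D (monomorphic, S = 0) are dropped and counted.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = np.random.default_rng(seed)
    vals = np.empty(reps)
    n_undef = 0
    k = 0
    for _ in range(reps):
        counts = simulate_neutral_gene(n, theta, rng, fixed_s=fixed_s)
        _, _, _, d = sfs_statistics(counts, n)
        if np.isnan(d):
            n_undef += 1
        else:
            vals[k] = d
            k += 1
    return NullDistribution(
        n_chrom=n, theta=theta, reps=reps, values=np.sort(vals[:k]), seed=seed,
        n_undefined=n_undef,
    )


def empirical_p(observed_d: float, null: NullDistribution) -> float:
    """One-sided tail proportion in the direction of the observed sign.

    positive D: fraction of null values >= observed; negative D: fraction
    <= observed; observed exactly 0 returns 1 by convention. Raw proportion,
    no +1 correction.
    """
    if np.isnan(observed_d):
        raise UndefinedStatistic("observed D is undefined")
    v = null.values
    if v.size == 0:
        raise UndefinedStatistic("empty null distribution")
    if observed_d == 0:
        return 1.0
    if observed_d > 0:
        return float(np.sum(v >= observed_d) / v.size)
    return float(np.sum(v <= observed_d) / v.size)


class NullCache:
    """Cache of null distributions keyed by (n, S).

    With watterson or fixed_S conditioning the null depends on the gene only
    through its chromosome count and segregating-site count, so the per-gene
    ms loop collapses to a handful of unique distributions. Seeds are derived
    deterministically from the base seed and the key.
    """

    def __init__(self, reps: int = 9999, seed: int = 0, theta_source: str = "watterson"):
        if theta_source not in ("watterson", "pi", "fixed_S"):
            raise ValueError(f"unknown theta_source {theta_source!r}")
        self.reps = reps
        self.seed = seed
        self.theta_source = theta_source
        self._store: dict[tuple, NullDistribution] = {}

    def get(self, n: int, S: int, pi_total: float = float("nan")) -> NullDistribution:
        if self.theta_source == "pi":
            key = (n, round(float(pi_total), 10))
        else:
            key = (n, int(S))
        if key not in self._store:
            sub = (self.seed * 1_000_003 + hash(key)) % (2**31 - 1)
            if self.theta_source == "fixed_S":
                nd = null_distribution_D(n, 0.0, self.reps, sub, fixed_s=S)
            elif self.theta_source == "pi":
                nd = null_distribution_D(n, float(pi_total), self.reps, sub)
            else:
                nd = null_distribution_D(n, S / harmonic(n), self.reps, sub)
            self._store[key] = nd
        return self._store[key]
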