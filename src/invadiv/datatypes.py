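"""Core in-memory containers shared across the pipeline.

The analysis operates on unphased diploid genotypes at biallelic exonic SNPs
(dosage of the alternate allele: 0, 1, 2, or missing), grouped into short
coding "gene fragments" with a known reading frame, and on a sample-to-cluster
assignment. Coordinates are 1-based, inclusive, on the coding (transcript)
strand throughout; annotation must be pre-projected to transcript space.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = -1  # dosage sentinel


class DataIntegrityError(ValueError):
    """Input contradicts its own contract (e.g. ref allele mismatch)."""


class UndefinedStatistic(Exception):
    """A statistic has no defined value for this input (e.g. n < 2)."""


@dataclass
class GenotypeMatrix:
    """Samples x biallelic-SNP-sites alternate-allele dosage matrix.

    Attributes
    ----------
    sample_ids : list of str
    sites : pandas.DataFrame with columns ``transcript``, ``pos`` (1-based),
        ``ref``, ``alt`` (single bases), one row per retained site.
    dosage : int8 array (n_samples, n_sites); values in {0, 1, 2, MISSING}.
    gq, dp : optional float arrays of the same shape (per-genotype quality
        and depth); ``None`` when the source VCF lacks the field.
    """

    sample_ids: list[str]
    sites: pd.DataFrame
    dosage: np.ndarray
    gq: np.ndarray | None = None
    dp: np.ndarray | None = None

    def __post_init__(self) -> None:
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise DataIntegrityError("duplicate sample id in genotype matrix")
        if self.dosage.shape != (len(self.sample_ids), len(self.sites)):
            raise DataIntegrityError("dosage shape does not match samples x sites")
        dup = self.sites.duplicated(subset=["transcript", "pos"])
        if dup.any():
            raise DataIntegrityError("duplicate (transcript, pos) site")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def site_keys(self) -> list[tuple[str, int]]:
        return list(zip(self.sites["transcript"], self.sites["pos"].astype(int)))

    def take_sites(self, idx: np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            sample_ids=list(self.sample_ids),
            sites=self.sites.iloc[idx].reset_index(drop=True),
            dosage=self.dosage[:, idx].copy(),
            gq=None if self.gq is None else self.gq[:, idx].copy(),
            dp=None if self.dp is None else self.dp[:, idx].copy(),
        )

    def take_samples(self, names: list[str]) -> "GenotypeMatrix":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        idx = np.array([pos[s] for s in names], dtype=int)
        return GenotypeMatrix(
            sample_ids=list(names),
            sites=self.sites.copy(),
            dosage=self.dosage[idx],
            gq=None if self.gq is None else self.gq[idx],
            dp=None if self.dp is None else self.dp[idx],
        )

    def allele_counts(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-site (alt allele count, called chromosome count), pooled."""
        called = self.dosage != MISSING
        alt = np.where(called, self.dosage, 0).sum(axis=0)
        n = 2 * called.sum(axis=0)
        return alt.astype(int), n.astype(int)


@dataclass
class GeneFragment:
    """Covered coding intervals of one gene fragment, with reading frame.

    ``frame_offset`` is the 0-based position of the first covered base within
    its codon; ``coding_seq`` is the reference sequence of the covered ranges,
    concatenated in order.
    """

    gene_name: str
    transcript_id: str
    intervals: list[tuple[int, int]]  # 1-based inclusive, sorted, non-overlapping
    frame_offset: int
    coding_seq: str

    def __post_init__(self) -> None:
        self.intervals = [(int(a), int(b)) for a, b in self.intervals]
        prev_end = 0
        for a, b in self.intervals:
            if a > b or a <= prev_end:
                raise DataIntegrityError(
                    f"{self.gene_name}: intervals must be sorted, non-overlapping"
                )
            prev_end = b
        if len(self.coding_seq) != self.covered_len:
            raise DataIntegrityError(
                f"{self.gene_name}: coding_seq length {len(self.coding_seq)} != "
                f"covered length {self.covered_len}"
            )
        if self.frame_offset not in (0, 1, 2):
            raise DataIntegrityError(f"{self.gene_name}: frame_offset must be 0/1/2")
        self.coding_seq = self.coding_seq.upper()

    @property
    def covered_len(self) -> int:
        return sum(b - a + 1 for a, b in self.intervals)

    def offset_of(self, pos: int) -> int:
        """0-based index of transcript position ``pos`` within coding_seq."""
        off = 0
        for a, b in self.intervals:
            if a <= pos <= b:
                return off + (pos - a)
            off += b - a + 1
        raise DataIntegrityError(
            f"{self.gene_name}: position {pos} outside covered intervals"
        )

    def contains(self, pos: int) -> bool:
        return any(a <= pos <= b for a, b in self.intervals)


@dataclass
class ClusterMap:
    """Assignment of every sample to exactly one genetic cluster."""

    assignment: dict[str, str]

    @property
    def clusters(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.assignment.values():
            seen.setdefault(c, None)
        return list(seen)

    def counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for c in self.assignment.values():
            out[c] = out.get(c, 0) + 1
        return out

    def samples_of(self, cluster: str) -> list[str]:
        return [s for s, c in self.assignment.items() if c == cluster]

    def validate_against(self, gm: GenotypeMatrix) -> None:
        missing = [s for s in gm.sample_ids if s not in self.assignment]
        if missing:
            raise DataIntegrityError(f"samples without cluster assignment: {missing[:5]}")


@dataclass
class SiteEffect:
    """Coding effect (synonymous / nonsynonymous) of each retained SNP."""

    effect: dict[tuple[str, int], str]  # (transcript, pos) -> "syn" | "nonsyn"
    multi_snp_codon: dict[tuple[str, int], bool] = field(default_factory=dict)

    def class_of(self, key: tuple[str, int]) -> str:
        return self.effect[key]


@dataclass
class FilterReport:
    """Per-stage drop counts accumulated through the filtering cascade."""

    stages: list[tuple[str, int]] = field(default_factory=list)

    def log(self, stage: str, n_dropped: int) -> None:
        self.stages.append((stage, int(n_dropped)))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.stages, columns=["stage", "n_dropped"])
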