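"""Reading, filtering and annotating the analysis-ready SNP dataset.

The cascade mirrors targeted-capture practice for short coding fragments:
genotype-level GQ/DP masking, per-site missingness and minor-allele-count
filters, removal of putative duplicated (paralogous) fragments flagged by
extreme observed heterozygosity, selection of informative fragments, and
codon-aware classification of every SNP as synonymous or nonsynonymous
against the reference coding sequence.

Two filter profiles are first-class: the *diversity* profile (no MAC filter)
and the *outlier* profile (MAC >= 3) used by the differentiation scans.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq
from cyvcf2 import VCF

from .datatypes import (
    MISSING,
    ClusterMap,
    DataIntegrityError,
    FilterReport,
    GeneFragment,
    GenotypeMatrix,
    SiteEffect,
)

logger = logging.getLogger(__name__)

_BASES = ("A", "C", "G", "T")


class VcfParseError(ValueError):
    pass


# ---------------------------------------------------------------------------
# VCF input / output
# ---------------------------------------------------------------------------

def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Load biallelic SNP records from a VCF (v4.x) into a GenotypeMatrix.

    Non-biallelic and non-SNP records are dropped (count logged). Half-calls
    and ``./.`` genotypes are treated as missing. GQ and DP are read when the
    FORMAT declares them, otherwise left as ``None``.
    """
    path = str(path)
    try:
        vcf = VCF(path, gts012=True)
    except Exception as exc:  # cyvcf2 raises bare OSError on malformed input
        raise VcfParseError(f"cannot parse VCF {path!r}: {exc}") from exc
    samples = list(vcf.samples)
    if len(set(samples)) != len(samples):
        raise DataIntegrityError(f"duplicate sample id in VCF header of {path!r}")

    has_gq = "GQ" in {f for f in _format_ids(vcf)}
    has_dp = "DP" in {f for f in _format_ids(vcf)}

    recs, dosage_rows, gq_rows, dp_rows = [], [], [], []
    n_dropped = 0
    for var in vcf:
        if len(var.ALT) != 1 or not var.is_snp:
            n_dropped += 1
            continue
        recs.append((var.CHROM, var.POS, var.REF.upper(), var.ALT[0].upper()))
        # gts012: 0/1/2 = alt dosage, 3 = unknown (includes half-calls)
        gt = var.gt_types.copy()
        gt[gt == 3] = MISSING
        dosage_rows.append(gt.astype(np.int8))
        if has_gq:
            gq = var.format("GQ")
            gq_rows.append(
                np.full(len(samples), np.nan, dtype=np.float32)
                if gq is None
                else gq.astype(np.float32).reshape(-1)
            )
        if has_dp:
            dp = var.format("DP")
            dp_rows.append(
                np.full(len(samples), np.nan, dtype=np.float32)
                if dp is None
                else dp.astype(np.float32).reshape(-1)
            )
    if n_dropped:
        logger.info("read_vcf: dropped %d non-biallelic/non-SNP records", n_dropped)

    sites = pd.DataFrame(recs, columns=["transcript", "pos", "ref", "alt"])
    n_sites = len(sites)
    dosage = (
        np.stack(dosage_rows, axis=1)
        if n_sites
        else np.zeros((len(samples), 0), dtype=np.int8)
    )
    gq = np.stack(gq_rows, axis=1) if (has_gq and n_sites) else None
    dp = np.stack(dp_rows, axis=1) if (has_dp and n_sites) else None
    return GenotypeMatrix(sample_ids=samples, sites=sites, dosage=dosage, gq=gq, dp=dp)


def _format_ids(vcf: VCF) -> list[str]:
    ids = []
    for line in vcf.raw_header.splitlines():
        if line.startswith("##FORMAT=<ID="):
            ids.append(line.split("ID=", 1)[1].split(",", 1)[0])
    return ids


def write_vcf(gm: GenotypeMatrix, path: str | Path) -> None:
    """Emit the matrix as an uncompressed VCF v4.2 (GT:GQ:DP when present)."""
    fmt_fields = ["GT"]
    if gm.gq is not None:
        fmt_fields.append("GQ")
    if gm.dp is not None:
        fmt_fields.append("DP")
    gt_str = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=invadiv\n")
        for t in pd.unique(gm.sites["transcript"]):
            fh.write(f"##contig=<ID={t}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if gm.gq is not None:
            fh.write(
                '##FORMAT=<ID=GQ,Number=1,Type=Integer,'
                'Description="Genotype quality">\n'
            )
        if gm.dp is not None:
            fh.write(
                '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n'
            )
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.sample_ids)
            + "\n"
        )
        for j in range(gm.n_sites):
            row = gm.sites.iloc[j]
            cells = []
            for i in range(gm.n_samples):
                parts = [gt_str[int(gm.dosage[i, j])]]
                if gm.gq is not None:
                    v = gm.gq[i, j]
                    parts.append("." if np.isnan(v) else str(int(round(v))))
                if gm.dp is not None:
                    v = gm.dp[i, j]
                    parts.append("." if np.isnan(v) else str(int(round(v))))
                cells.append(":".join(parts))
            fh.write(
                f"{row.transcript}\t{int(row.pos)}\t.\t{row.ref}\t{row.alt}\t.\t.\t.\t"
                + ":".join(fmt_fields)
                + "\t"
                + "\t".join(cells)
                + "\n"
            )


# ---------------------------------------------------------------------------
# Annotation / cluster-map input
# ---------------------------------------------------------------------------

def read_fragments(path: str | Path) -> list[GeneFragment]:
    """Read the gene-fragment annotation TSV.

    Columns: gene, transcript, start, end, frame_offset, coding_seq. A gene
    covered by several exon intervals occupies several rows; coding_seq may
    be given on the first row only (the concatenated covered sequence).
    """
    df = pd.read_csv(path, sep="\t", dtype={"coding_seq": str})
    frags = []
    for (gene, transcript), grp in df.groupby(["gene", "transcript"], sort=False):
        grp = grp.sort_values("start")
        seq = "".join(s for s in grp["coding_seq"] if isinstance(s, str))
        frags.append(
            GeneFragment(
                gene_name=str(gene),
                transcript_id=str(transcript),
                intervals=list(zip(grp["start"], grp["end"])),
                frame_offset=int(grp["frame_offset"].iloc[0]),
                coding_seq=seq,
            )
        )
    return frags


def read_cluster_map(path: str | Path) -> ClusterMap:
    df = pd.read_csv(path, sep="\t")
    return ClusterMap(assignment=dict(zip(df["sample"].astype(str), df["cluster"].astype(str))))


# ---------------------------------------------------------------------------
# Filtering cascade
# ---------------------------------------------------------------------------

def mask_and_filter_sites(
    gm: GenotypeMatrix,
    gq_min: float = 80.0,
    dp_min: float = 10.0,
    max_missing: float = 0.15,
    report: FilterReport | None = None,
) -> GenotypeMatrix:
    """Mask low-confidence genotypes, then drop high-missingness sites.

    Genotypes with GQ < gq_min or DP < dp_min become missing *before* the
    per-site missing fraction is evaluated; sites with missing fraction
    strictly above ``max_missing`` are removed.
    """
    if not 0 <= max_missing <= 1:
        raise ValueError("max_missing must be in [0, 1]")
    if (gq_min > 0 and gm.gq is None) or (dp_min > 0 and gm.dp is None):
        raise ValueError(
            "GQ/DP thresholds require GQ/DP fields in the genotype matrix"
        )
    dosage = gm.dosage.copy()
    if gm.gq is not None and gq_min > 0:
        dosage[np.nan_to_num(gm.gq, nan=-1.0) < gq_min] = MISSING
    if gm.dp is not None and dp_min > 0:
        dosage[np.nan_to_num(gm.dp, nan=-1.0) < dp_min] = MISSING
    miss_frac = (dosage == MISSING).mean(axis=0)
    keep = np.flatnonzero(miss_frac <= max_missing)
    out = GenotypeMatrix(
        sample_ids=list(gm.sample_ids),
        sites=gm.sites.iloc[keep].reset_index(drop=True),
        dosage=dosage[:, keep],
        gq=None if gm.gq is None else gm.gq[:, keep].copy(),
        dp=None if gm.dp is None else gm.dp[:, keep].copy(),
    )
    n_drop = gm.n_sites - out.n_sites
    logger.info("mask_and_filter_sites: removed %d sites (missingness)", n_drop)
    if report is not None:
        report.log("missingness", n_drop)
    return out


def filter_mac(
    gm: GenotypeMatrix, mac_min: int = 3, report: FilterReport | None = None
) -> GenotypeMatrix:
    """Drop sites whose pooled minor-allele count is below ``mac_min``."""
    if mac_min < 0:
        raise ValueError("mac_min must be >= 0")
    alt, n = gm.allele_counts()
    mac = np.minimum(alt, n - alt)
    keep = np.flatnonzero(mac >= mac_min)
    out = gm.take_sites(keep)
    n_drop = gm.n_sites - out.n_sites
    logger.info("filter_mac: removed %d sites (MAC < %d)", n_drop, mac_min)
    if report is not None:
        report.log(f"mac<{mac_min}", n_drop)
    return out


def drop_duplicate_fragments(
    gm: GenotypeMatrix,
    frags: list[GeneFragment],
    het_max: float = 0.9,
    report: FilterReport | None = None,
) -> tuple[GenotypeMatrix, list[GeneFragment]]:
    """Remove fragments with any SNP of observed heterozygosity > het_max.

    Near-universal heterozygosity across the whole dataset is the signature
    of collapsed paralogs; the whole fragment is discarded, not just the site.
    """
    if not 0 < het_max <= 1:
        raise ValueError("het_max must be in (0, 1]")
    called = gm.dosage != MISSING
    n_called = called.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        het = np.where(n_called > 0, (gm.dosage == 1).sum(axis=0) / n_called, 0.0)
    flagged = set(gm.sites["transcript"].values[het > het_max])
    keep_frags = [f for f in frags if f.transcript_id not in flagged]
    drop_tx = {f.transcript_id for f in frags} - {f.transcript_id for f in keep_frags}
    keep = np.flatnonzero(~gm.sites["transcript"].isin(drop_tx).values)
    out = gm.take_sites(keep)
    logger.info(
        "drop_duplicate_fragments: removed %d fragments, %d sites",
        len(frags) - len(keep_frags),
        gm.n_sites - out.n_sites,
    )
    if report is not None:
        report.log("duplicate_fragments", gm.n_sites - out.n_sites)
    return out, keep_frags


def select_informative_fragments(
    gm: GenotypeMatrix,
    frags: list[GeneFragment],
    min_len: int = 150,
    min_snps: int = 3,
    report: FilterReport | None = None,
) -> tuple[GenotypeMatrix, list[GeneFragment]]:
    """Keep fragments long enough and polymorphic enough for SFS statistics.

    A fragment is retained iff covered_len >= min_len AND its polymorphic
    site count (sites present in ``gm``) >= min_snps.
    """
    if min_len <= 0 or min_snps < 0:
        raise ValueError("min_len must be > 0 and min_snps >= 0")
    tx_in_gm = set(gm.sites["transcript"])
    for f in frags:
        if f.transcript_id not in tx_in_gm:
            # fragments with zero retained SNPs are legal (they just fail
            # min_snps); an unknown transcript with min_snps == 0 is an error
            if min_snps == 0:
                raise ValueError(
                    f"fragment {f.gene_name} references transcript "
                    f"{f.transcript_id} absent from the genotype matrix"
                )
    counts = gm.sites["transcript"].value_counts()
    kept = [
        f
        for f in frags
        if f.covered_len >= min_len and counts.get(f.transcript_id, 0) >= min_snps
    ]
    keep_tx = {f.transcript_id for f in kept}
    keep = np.flatnonzero(gm.sites["transcript"].isin(keep_tx).values)
    out = gm.take_sites(keep)
    logger.info(
        "select_informative_fragments: kept %d/%d fragments", len(kept), len(frags)
    )
    if report is not None:
        report.log("uninformative_fragments", gm.n_sites - out.n_sites)
    return out, kept


# ---------------------------------------------------------------------------
# Synonymous / nonsynonymous classification
# ---------------------------------------------------------------------------

def _codon_context(frag: GeneFragment, pos: int) -> tuple[str, int, int]:
    """Reference codon containing ``pos``, the within-codon index, and the
    codon's index. Raises if the codon is not fully covered."""
    i = frag.offset_of(pos)
    phase = (i + frag.frame_offset) % 3
    start = i - phase
    if start < 0 or start + 3 > len(frag.coding_seq):
        raise DataIntegrityError(
            f"{frag.gene_name}:{pos}: codon not fully covered by the fragment"
        )
    return frag.coding_seq[start : start + 3], phase, (i + frag.frame_offset) // 3


def classify_site_effects(
    frags: list[GeneFragment], gm: GenotypeMatrix
) -> SiteEffect:
    """Classify every SNP as synonymous or nonsynonymous.

    The reference codon is located via the fragment's frame; the alternate
    allele is substituted at the SNP position and the two codons translated
    under the standard genetic code. Codons containing more than one SNP are
    flagged ``multi_snp_codon`` (each SNP still classified against the
    reference background). Changes creating a stop codon count as
    nonsynonymous.
    """
    by_tx = {f.transcript_id: f for f in frags}
    effect: dict[tuple[str, int], str] = {}
    multi: dict[tuple[str, int], bool] = {}
    codon_members: dict[tuple[str, int], list[tuple[str, int]]] = {}
    for _, row in gm.sites.iterrows():
        tx, pos, ref, alt = row.transcript, int(row.pos), row.ref, row.alt
        if tx not in by_tx:
            continue
        frag = by_tx[tx]
        codon, phase, codon_idx = _codon_context(frag, pos)
        if codon[phase] != ref:
            raise DataIntegrityError(
                f"{frag.gene_name}:{pos}: VCF ref {ref} != coding_seq {codon[phase]}"
            )
        alt_codon = codon[:phase] + alt + codon[phase + 1 :]
        aa_ref = str(Seq(codon).translate(table=standard_dna_table))
        aa_alt = str(Seq(alt_codon).translate(table=standard_dna_table))
        effect[(tx, pos)] = "syn" if aa_ref == aa_alt else "nonsyn"
        codon_members.setdefault((tx, codon_idx), []).append((tx, pos))
    for members in codon_members.values():
        for key in members:
            multi[key] = len(members) > 1
    return SiteEffect(effect=effect, multi_snp_codon=multi)


def nei_gojobori_site_counts(frag: GeneFragment) -> tuple[float, float]:
    """Nei–Gojobori (1986) potential synonymous/nonsynonymous site counts.

    Each complete covered codon contributes 3 sites split by the fraction of
    the 3 possible single-base changes at each position that preserve the
    amino acid. Incomplete edge codons are skipped; substitutions to stop
    codons count as nonsynonymous. Returns ``(syn_sites, nonsyn_sites)``.
    """
    seq = frag.coding_seq
    fo = frag.frame_offset
    start = (3 - fo) % 3  # first complete codon start within coding_seq
    syn = 0.0
    table = standard_dna_table.forward_table
    for c0 in range(start, len(seq) - 2, 3):
        codon = seq[c0 : c0 + 3]
        if any(b not in _BASES for b in codon) or codon not in table:
            continue  # ambiguous base or reference stop codon
        aa = table[codon]
        for phase in range(3):
            n_syn = sum(
                1
                for b in _BASES
                if b != codon[phase]
                and table.get(codon[:phase] + b + codon[phase + 1 :]) == aa
            )
            syn += n_syn / 3.0
    total = 3.0 * sum(
        1 for c0 in range(start, len(seq) - 2, 3) if seq[c0 : c0 + 3] in table
    )
    return syn, total - syn


def effect_table(eff: SiteEffect, gm: GenotypeMatrix) -> pd.DataFrame:
    """Long-format site-effect table (transcript, pos, ref, alt, class, flag)."""
    rows = []
    for _, r in gm.sites.iterrows():
        key = (r.transcript, int(r.pos))
        if key in eff.effect:
            rows.append(
                (
                    r.transcript,
                    int(r.pos),
                    r.ref,
                    r.alt,
                    eff.effect[key],
                    bool(eff.multi_snp_codon.get(key, False)),
                )
            )
    return pd.DataFrame(
        rows, columns=["transcript", "pos", "ref", "alt", "effect", "multi_snp_codon"]
    )
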