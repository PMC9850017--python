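"""Filtering cascade, VCF round-trip and codon-effect classification."""

import numpy as np
import pytest
from Bio.Seq import Seq

from invadiv import variant_io
from invadiv.datatypes import DataIntegrityError, FilterReport

from conftest import make_fragment, make_gm

VCF_HEADER = """##fileformat=VCFv4.2
##contig=<ID=tx1>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts0\ts1
"""


def test_read_vcf_keeps_biallelic_snps_only(tmp_path):
    body = (
        "tx1\t1\t.\tA\tG\t.\t.\t.\tGT\t0/1\t1/1\n"
        "tx1\t2\t.\tC\tT,G\t.\t.\t.\tGT\t0/1\t0/2\n"   # triallelic: dropped
        "tx1\t3\t.\tA\tAT\t.\t.\t.\tGT\t0/1\t0/0\n"    # indel: dropped
        "tx1\t4\t.\tG\tA\t.\t.\t.\tGT\t./.\t0/1\n"     # ./. -> missing
        "tx1\t5\t.\tT\tC\t.\t.\t.\tGT\t0/0\t0/1\n"
    )
    p = tmp_path / "x.vcf"
    p.write_text(VCF_HEADER + body)
    gm = variant_io.read_vcf(p)
    assert gm.n_sites == 3
    assert list(gm.sites["pos"]) == [1, 4, 5]
    assert gm.dosage[0, 1] == -1  # ./. is missing


def test_vcf_round_trip_identity(small_sim, tmp_path):
    """A simulated matrix survives write -> read unchanged."""
    gm = small_sim.gm
    p = tmp_path / "rt.vcf"
    variant_io.write_vcf(gm, p)
    back = variant_io.read_vcf(p)
    assert back.sample_ids == gm.sample_ids
    assert back.sites[["transcript", "pos", "ref", "alt"]].equals(
        gm.sites[["transcript", "pos", "ref", "alt"]]
    )
    np.testing.assert_array_equal(back.dosage, gm.dosage)
    np.testing.assert_allclose(back.gq, gm.gq)
    np.testing.assert_allclose(back.dp, gm.dp)


def test_read_vcf_malformed_raises(tmp_path):
    p = tmp_path / "bad.vcf"
    p.write_text("this is not a vcf\n")
    with pytest.raises(variant_io.VcfParseError):
        variant_io.read_vcf(p)


@pytest.mark.parametrize(
    "n_missing,expected_kept", [(5, False), (4, True)]
)
def test_missingness_boundary(n_missing, expected_kept):
    """5/30 (0.1667) exceeds the 0.15 threshold, 4/30 (0.133) does not."""
    dos = np.ones((30, 1), dtype=np.int8)
    dos[:n_missing, 0] = -1
    gm = make_gm(dos, gq=np.full((30, 1), 99.0), dp=np.full((30, 1), 50.0))
    out = variant_io.mask_and_filter_sites(gm, 80, 10, max_missing=0.15)
    assert (out.n_sites == 1) is expected_kept


def test_mask_high_quality_identity():
    dos = np.array([[0, 1], [2, 1], [1, 0]], dtype=np.int8)
    gm = make_gm(dos, gq=np.full((3, 2), 99.0), dp=np.full((3, 2), 50.0))
    out = variant_io.mask_and_filter_sites(gm, 80, 10, 0.15)
    np.testing.assert_array_equal(out.dosage, dos)


def test_mask_requires_fields_when_thresholds_positive():
    gm = make_gm(np.zeros((4, 2), dtype=np.int8))
    with pytest.raises(ValueError):
        variant_io.mask_and_filter_sites(gm, 80, 10, 0.15)


def test_filter_mac_boundary_and_identity():
    # site 0: alt on 2 chromosomes -> removed at mac_min=3; site 1: alt on 3
    dos = np.zeros((10, 2), dtype=np.int8)
    dos[0, 0] = 2
    dos[0, 1] = 2
    dos[1, 1] = 1
    gm = make_gm(dos)
    out = variant_io.filter_mac(gm, mac_min=3)
    assert list(out.sites["pos"]) == [2]
    np.testing.assert_array_equal(
        variant_io.filter_mac(gm, mac_min=0).dosage, dos
    )


def test_filter_mac_matches_brute_force_recount():
    rng = np.random.default_rng(0)
    dos = rng.integers(-1, 3, size=(20, 40)).astype(np.int8)
    gm = make_gm(dos, positions=list(range(1, 41)))
    out = variant_io.filter_mac(gm, mac_min=3)
    expected = []
    for j in range(40):
        col = dos[:, j]
        called = col[col >= 0]
        alt = int(called.sum())
        n = 2 * len(called)
        if min(alt, n - alt) >= 3:
            expected.append(j + 1)
    assert list(out.sites["pos"]) == expected


def test_drop_duplicate_fragments_planted_paralog():
    """A site heterozygous in 28/30 samples (0.933 > 0.9) kills its fragment."""
    dos = np.zeros((30, 2), dtype=np.int8)
    dos[:28, 0] = 1          # tx1: paralog-like site
    dos[:5, 1] = 1
    gm = make_gm(dos, transcripts=["tx1", "tx2"], positions=[3, 3])
    frags = [make_fragment("gA", "tx1", "ATG" * 4), make_fragment("gB", "tx2", "ATG" * 4)]
    out, kept = variant_io.drop_duplicate_fragments(gm, frags, het_max=0.9)
    assert [f.gene_name for f in kept] == ["gB"]
    assert set(out.sites["transcript"]) == {"tx2"}
    # all-below-threshold input is untouched
    out2, kept2 = variant_io.drop_duplicate_fragments(
        gm.take_sites(np.array([1])), [frags[1]], het_max=0.9
    )
    assert len(kept2) == 1 and out2.n_sites == 1


@pytest.mark.parametrize(
    "length,n_snps,kept",
    [(140, 5, False), (660, 2, False), (167, 3, True)],
)
def test_select_informative_fragments(length, n_snps, kept):
    seq = ("ATG" * ((length + 2) // 3))[:length]
    frag = make_fragment("g", "tx1", seq)
    dos = np.zeros((6, n_snps), dtype=np.int8)
    dos[0, :] = 1
    gm = make_gm(dos, positions=list(range(1, n_snps + 1)))
    _, frags = variant_io.select_informative_fragments(gm, [frag], 150, 3)
    assert (len(frags) == 1) is kept


def test_classify_effects_code_table_cases():
    # TTA codon, third-position A->G (Leu->Leu) syn; ATG first A->G nonsyn
    frag = make_fragment("g", "tx1", "ATGTTA")
    dos = np.zeros((4, 2), dtype=np.int8)
    dos[0] = 1
    gm = make_gm(dos, positions=[1, 6])
    gm.sites.loc[0, ["ref", "alt"]] = ["A", "G"]
    gm.sites.loc[1, ["ref", "alt"]] = ["A", "G"]
    eff = variant_io.classify_site_effects([frag], gm)
    assert eff.effect[("tx1", 1)] == "nonsyn"  # ATG -> GTG, Met -> Val
    assert eff.effect[("tx1", 6)] == "syn"     # TTA -> TTG, both Leu
    assert not eff.multi_snp_codon[("tx1", 1)]


def test_classify_effects_multi_snp_codon_flag():
    frag = make_fragment("g", "tx1", "ATGTTA")
    dos = np.zeros((4, 2), dtype=np.int8)
    dos[0] = 1
    gm = make_gm(dos, positions=[4, 6])
    gm.sites.loc[0, ["ref", "alt"]] = ["T", "C"]
    gm.sites.loc[1, ["ref", "alt"]] = ["A", "G"]
    eff = variant_io.classify_site_effects([frag], gm)
    assert eff.multi_snp_codon[("tx1", 4)] and eff.multi_snp_codon[("tx1", 6)]


def test_classify_effects_ref_mismatch_raises():
    frag = make_fragment("g", "tx1", "ATGTTA")
    dos = np.zeros((2, 1), dtype=np.int8)
    gm = make_gm(dos, positions=[2])
    gm.sites.loc[0, ["ref", "alt"]] = ["C", "G"]  # coding_seq has T at pos 2
    with pytest.raises(DataIntegrityError):
        variant_io.classify_site_effects([frag], gm)


def test_classify_effects_matches_translation_oracle():
    """Random fixture: per-SNP class equals whole-protein translate-and-compare."""
    rng = np.random.default_rng(1)
    bases = "ACGT"
    codons = [a + b + c for a in bases for b in bases for c in bases
              if Seq(a + b + c).translate() != "*"]
    seq = "".join(rng.choice(codons) for _ in range(40))
    frag = make_fragment("g", "tx1", seq)
    positions, refs, alts = [], [], []
    for pos in rng.choice(len(seq), size=100, replace=False):
        ref = seq[pos]
        positions.append(int(pos) + 1)
        refs.append(ref)
        alts.append(str(rng.choice([b for b in bases if b != ref])))
    order = np.argsort(positions)
    dos = np.zeros((4, 100), dtype=np.int8)
    dos[0] = 1
    gm = make_gm(dos, positions=[positions[i] for i in order])
    gm.sites["ref"] = [refs[i] for i in order]
    gm.sites["alt"] = [alts[i] for i in order]
    eff = variant_io.classify_site_effects([frag], gm)
    prot_ref = str(Seq(seq).translate())
    for _, row in gm.sites.iterrows():
        mutated = seq[: row.pos - 1] + row.alt + seq[row.pos :]
        prot_alt = str(Seq(mutated).translate())
        expected = "syn" if prot_alt == prot_ref else "nonsyn"
        assert eff.effect[("tx1", row.pos)] == expected


def test_every_retained_snp_is_classified(small_sim):
    """#syn + #nonsyn equals the number of retained coding SNPs."""
    gm, frags = small_sim.gm, small_sim.fragments
    eff = variant_io.classify_site_effects(frags, gm)
    classes = [eff.effect[k] for k in gm.site_keys()]
    assert len(classes) == gm.n_sites
    assert set(classes) <= {"syn", "nonsyn"}


def test_nei_gojobori_hand_value():
    # TTA (Leu): pos1 1/3 syn (CTA), pos2 0, pos3 1/3 syn (TTG) -> 2/3 syn
    frag = make_fragment("g", "tx1", "TTA")
    syn, nonsyn = variant_io.nei_gojobori_site_counts(frag)
    assert syn == pytest.approx(2 / 3)
    assert nonsyn == pytest.approx(3 - 2 / 3)


def test_filter_report_accumulates_stages():
    dos = np.zeros((10, 3), dtype=np.int8)
    dos[0, 0] = 2
    gm = make_gm(dos, gq=np.full((10, 3), 99.0), dp=np.full((10, 3), 50.0))
    rep = FilterReport()
    out = variant_io.mask_and_filter_sites(gm, 80, 10, 0.15, report=rep)
    variant_io.filter_mac(out, 3, report=rep)
    df = rep.to_frame()
    assert list(df["stage"]) == ["missingness", "mac<3"]
    assert df["n_dropped"].tolist() == [0, 3]
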