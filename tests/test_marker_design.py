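import numpy as np
import pytest

from haplomark.enzyme_kit import Enzyme
from haplomark.locus_io import EnzymeCatalog, LocusSequence
from haplomark.marker_design import (
    DesignConfig,
    DesignError,
    dcaps_candidates,
    design_cascade,
    design_caps,
    design_dcaps,
    design_indel,
    design_parms,
    design_primer_pair,
    gc_percent,
    name_marker,
    select_target_variants,
)
from haplomark.variant_haplotype import Variant, label_position

from .oracles import dcaps_placements

RELAXED = DesignConfig(tm_range=(0.0, 150.0), gc_range=(0.0, 100.0))
# for oracle-equivalence checks every primer filter must be non-binding, so
# only the search geometry is compared
ORACLE_CFG = DesignConfig(tm_range=(0.0, 150.0), gc_range=(0.0, 100.0),
                          max_mono_run=99)


def _random_locus(seed, n=800, atg=300):
    rng = np.random.default_rng(seed)
    seq = "".join(rng.choice(list("ACGT"), size=n))
    return LocusSequence("NIP", "g", seq, atg, n - 1)


# ---------------------------------------------------------------------------
# target selection and naming


def test_select_target_variants_private_to_targets(panel):
    cand = select_target_variants(panel.truth_haps, panel.truth_matrix, {"HapB"})
    truth_profile = panel.truth_haps.get("HapB").profile
    assert {v.key for v in cand} == truth_profile  # HapB-private, HapC excluded
    cand_c = select_target_variants(panel.truth_haps, panel.truth_matrix, {"HapC"})
    assert {v.key for v in cand_c} == panel.truth_haps.get("HapC").profile


def test_variant_shared_with_other_haplotype_excluded(panel):
    # targeting HapB and HapC jointly returns nothing: no variant is shared
    cand = select_target_variants(panel.truth_haps, panel.truth_matrix,
                                  {"HapB", "HapC"})
    assert cand == []


@pytest.mark.parametrize(
    "gene,region,mtype,expected",
    [
        ("NPF6.1", "5U", "Indel", "NPF6.1 5U ID"),
        ("SBM1", "E3", "CAPS", "SBM1 E3 S"),
        ("DNR1", "I4", "Indel", "DNR1 I4 ID"),
        ("NGR5", "I6", "PARMS", "NGR5 I6 S"),
        ("NAC42", "3U", "dCAPS", "NAC42 3U S"),
    ],
)
def test_name_marker_scheme(gene, region, mtype, expected):
    assert name_marker(gene, region, mtype) == expected


# ---------------------------------------------------------------------------
# primer pairs


def test_primer_pair_deterministic(rng):
    template = "".join(rng.choice(list("ACGT"), size=400))
    p1 = design_primer_pair(template, (180, 200), (100, 300))
    p2 = design_primer_pair(template, (180, 200), (100, 300))
    assert p1 == p2
    assert 100 <= p1.amplicon_len <= 300
    assert p1.fwd_start + len(p1.fwd) <= 180
    assert p1.amplicon_end - len(p1.rev) > 200


def test_primer_pair_short_template_fails():
    with pytest.raises(DesignError, match="shorter than"):
        design_primer_pair("ACGT" * 12, (20, 25), (100, 300))


def test_gc_percent_published_primer():
    assert gc_percent("TCATTGACCTACGGTTGC") == pytest.approx(50.0)


# ---------------------------------------------------------------------------
# Indel stage


def _indel_variant(locus, position, length):
    off = locus.atg_offset + (position - 1 if position > 0 else position)
    deleted = locus.seq[off:off + length]
    return Variant(position, "DEL", deleted, "-", "5U" if position < 0 else "E1", -length)


def test_design_indel_expected_sizes():
    locus = _random_locus(3)
    v = _indel_variant(locus, -120, 20)
    m = design_indel(v, locus, RELAXED, gene_label="TOY")
    assert m.mtype == "Indel" and m.enzyme is None
    assert 100 <= m.expected["ref"][0] <= 300
    assert m.expected["alt"][0] == m.expected["ref"][0] - 20
    assert m.name == "TOY 5U ID"


def test_design_indel_below_minimum_fails():
    locus = _random_locus(4)
    v = _indel_variant(locus, -120, 3)
    with pytest.raises(DesignError, match="outside"):
        design_indel(v, locus, RELAXED)


def test_design_indel_structural_override():
    locus = _random_locus(5, n=2600, atg=1200)
    v = _indel_variant(locus, -900, 620)  # DEP1-scale event
    with pytest.raises(DesignError):
        design_indel(v, locus, RELAXED)
    m = design_indel(v, locus, RELAXED, structural=True)
    assert m.rule_fired == "structural"
    assert any("override" in n for n in m.notes)
    assert m.expected["alt"][0] == m.expected["ref"][0] - 620


# ---------------------------------------------------------------------------
# CAPS stage


def _plant(locus, offset, motif):
    seq = locus.seq[:offset] + motif + locus.seq[offset + len(motif):]
    return LocusSequence(locus.accession, locus.gene_id, seq, locus.atg_offset,
                         locus.stop_offset)


def test_design_caps_site_created_by_alt():
    locus = _plant(_random_locus(6), 400, "TCGT")  # alt T>A completes TCGA
    snp = Variant(label_position(403, locus), "SNP", locus.seq[403], "A", "E1")
    cat = EnzymeCatalog([Enzyme("TaqI", "TCGA", 1)])
    m = design_caps(snp, locus, RELAXED, cat)
    assert m.enzyme.name == "TaqI"
    assert len(m.expected["alt"]) == 2 and len(m.expected["ref"]) == 1
    assert sum(m.expected["alt"]) == m.expected["ref"][0]
    assert min(m.expected["alt"]) >= RELAXED.min_cut_fragment


def test_design_caps_site_destroyed_by_alt():
    locus = _plant(_random_locus(7), 400, "TCGA")
    snp = Variant(label_position(401, locus), "SNP", "C", "T", "E1")
    cat = EnzymeCatalog([Enzyme("TaqI", "TCGA", 1)])
    m = design_caps(snp, locus, RELAXED, cat)
    assert len(m.expected["ref"]) == 2 and len(m.expected["alt"]) == 1


def test_design_caps_no_site_fails():
    locus = _random_locus(8)
    # pick a SNP position where neither allele touches a TaqI site
    off = 400
    seq = locus.seq[:off - 4] + "AAAACAAAA" + locus.seq[off + 5:]
    locus = LocusSequence("NIP", "g", seq, locus.atg_offset, locus.stop_offset)
    snp = Variant(label_position(off, locus), "SNP", "C", "G", "E1")
    cat = EnzymeCatalog([Enzyme("TaqI", "TCGA", 1)])
    with pytest.raises(DesignError, match="CAPS infeasible"):
        design_caps(snp, locus, RELAXED, cat)


# ---------------------------------------------------------------------------
# dCAPS stage


def _dcaps_toy(seed=5):
    """A locus where TaqI dCAPS needs one engineered base: genomic TAGT,
    SNP T>A at the site's last position; engineering A->C makes TCGA."""
    locus = _plant(_random_locus(seed, n=700, atg=200), 427, "TAGT")
    snp = Variant(label_position(430, locus), "SNP", "T", "A", "E1")
    return locus, snp


def test_design_dcaps_engineered_primer():
    locus, snp = _dcaps_toy()
    cat = EnzymeCatalog([Enzyme("TaqI", "TCGA", 1)])
    m = design_dcaps(snp, locus, RELAXED, cat)
    eng = m.engineered_positions("F")
    assert len(eng) == 1
    idx, base = eng[0]
    primer = m.primers["F"]
    # engineered base in the -2..-6 window, never the 3'-terminal base
    assert 1 <= len(primer) - 1 - idx <= 5
    # cut class digests into a short primer-side fragment plus a long one
    cut = m.expected["ref"] if len(m.expected["ref"]) > 1 else m.expected["alt"]
    assert len(cut) == 2 and min(cut) < len(primer) + 4


def test_dcaps_search_matches_brute_force_enumeration():
    # compact toy context so exhaustive enumeration stays cheap
    rng = np.random.default_rng(9)
    seq = "".join(rng.choice(list("ACGT"), size=110))
    seq = seq[:77] + "TAGT" + seq[81:]
    locus = LocusSequence("NIP", "g", seq, 20, 109)
    snp = Variant(label_position(80, locus), "SNP", "T", "A", "E1")
    cat = EnzymeCatalog([Enzyme("TaqI", "TCGA", 1), Enzyme("DdeI", "CTNAG", 1)])
    cands = dcaps_candidates(snp, locus, ORACLE_CFG, cat)
    got = {(c["enzyme"].name, c["primer_start"], len(c["primer"]), c["cut_class"])
           for c in cands}
    expected = dcaps_placements(
        locus.seq, 80, snp.ref_allele, snp.alt_allele, cat,
        range(ORACLE_CFG.primer_len[0], ORACLE_CFG.primer_len[1] + 1),
    )
    assert got == expected
    assert got  # the toy context is engineerable


def test_dcaps_never_engineers_terminal_base():
    locus, snp = _dcaps_toy(12)
    cat = EnzymeCatalog([Enzyme("TaqI", "TCGA", 1)])
    for cand in dcaps_candidates(snp, locus, RELAXED, cat):
        L = len(cand["primer"])
        for idx, _ in cand["engineered"]:
            assert idx != L - 1
            assert 1 <= L - 1 - idx <= 5


# ---------------------------------------------------------------------------
# PARMS stage


def test_design_parms_primer_structure():
    locus = _random_locus(13)
    snp = Variant(label_position(420, locus), "SNP", locus.seq[420],
                  "A" if locus.seq[420] != "A" else "G", "E1")
    m = design_parms(snp, locus, RELAXED)
    fc, ft, r = m.primers["FC"], m.primers["FT"], m.primers["R"]
    assert fc.startswith(RELAXED.tail_fam) and ft.startswith(RELAXED.tail_hex)
    core_c = fc[len(RELAXED.tail_fam):]
    core_t = ft[len(RELAXED.tail_hex):]
    assert core_c[:-1] == core_t[:-1]
    assert core_c[-1] == snp.ref_allele and core_t[-1] == snp.alt_allele
    assert m.expected == {"ref": "FAM", "alt": "HEX"}


def test_design_parms_requires_tails():
    locus = _random_locus(14)
    snp = Variant(label_position(420, locus), "SNP", locus.seq[420],
                  "A" if locus.seq[420] != "A" else "G", "E1")
    cfg = DesignConfig(tm_range=(0.0, 150.0), gc_range=(0.0, 100.0),
                       tail_fam="", tail_hex="")
    with pytest.raises(DesignError, match="tails"):
        design_parms(snp, locus, cfg)


# ---------------------------------------------------------------------------
# cascade priority


def test_cascade_prefers_indel_over_snp(panel):
    cand = select_target_variants(panel.truth_haps, panel.truth_matrix, {"HapB"})
    assert any(v.vtype != "SNP" for v in cand) and any(v.vtype == "SNP" for v in cand)
    m = design_cascade(cand, panel.ref_locus, gene_label="SYN")
    assert m.mtype == "Indel" and m.rule_fired == "indel"


def test_cascade_reaches_caps_without_indel():
    locus = _plant(_random_locus(6), 400, "TCGT")
    snp = Variant(label_position(403, locus), "SNP", locus.seq[403], "A", "E1")
    cat = EnzymeCatalog([Enzyme("TaqI", "TCGA", 1)])
    m = design_cascade([snp], locus, cfg=RELAXED, enzymes=cat)
    assert m.mtype == "CAPS"


def test_cascade_reaches_dcaps_when_caps_fails():
    locus, snp = _dcaps_toy()
    cat = EnzymeCatalog([Enzyme("TaqI", "TCGA", 1)])
    m = design_cascade([snp], locus, cfg=RELAXED, enzymes=cat)
    assert m.mtype == "dCAPS"


def test_cascade_falls_through_to_parms():
    locus = _random_locus(13)
    snp = Variant(label_position(420, locus), "SNP", locus.seq[420],
                  "A" if locus.seq[420] != "A" else "G", "E1")
    m = design_cascade([snp], locus, cfg=RELAXED, enzymes=EnzymeCatalog([]))
    assert m.mtype == "PARMS" and m.rule_fired == "parms"


def test_cascade_no_design_lists_stage_reasons():
    locus = _random_locus(15)
    v = _indel_variant(locus, -120, 3)  # below the indel window, no SNPs
    cfg = DesignConfig(tm_range=(0.0, 150.0), gc_range=(0.0, 100.0),
                       allow_structural_override=False)
    with pytest.raises(DesignError) as exc:
        design_cascade([v], locus, cfg=cfg, enzymes=EnzymeCatalog([]))
    assert set(exc.value.failures) >= {"indel", "caps", "dcaps", "parms"}
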