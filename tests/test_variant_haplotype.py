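import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from haplomark.locus_io import GeneModel, LocusSequence
from haplomark.variant_haplotype import (
    AlignParams,
    Variant,
    align_to_reference,
    annotate_region,
    build_matrix,
    call_variants,
    flag_nd,
    group_haplotypes,
    label_position,
    position_to_offset,
)

from .conftest import random_locus
from .oracles import affine_optimum


def _locus(seq, acc="Q", atg=None):
    atg = len(seq) // 3 if atg is None else atg
    return LocusSequence(acc, "g", seq, atg, len(seq) - 1)


# ---------------------------------------------------------------------------
# alignment


def test_identical_loci_align_gapless(rng):
    ref = random_locus(rng, 500)
    query = LocusSequence("Q", "g", ref.seq, ref.atg_offset, ref.stop_offset)
    aln = align_to_reference(query, ref)
    assert "-" not in aln.ref_row and "-" not in aln.query_row
    assert aln.score == 2.0 * 500


def test_single_deletion_alignment():
    ref = _locus("ACGTACGT", acc="NIP", atg=0)
    query = _locus("ACGACGT", atg=0)
    aln = align_to_reference(query, ref)
    assert aln.ref_row.count("-") == 0
    assert aln.query_row.count("-") == 1
    # one 1-bp gap, score = 7 matches + one gap of length 1
    assert aln.score == 7 * 2 + (-5 - 2)


@settings(max_examples=200, derandomize=True)
@given(st.data())
def test_aligner_matches_enumeration_oracle(data):
    a = data.draw(st.text(alphabet="ACGT", min_size=2, max_size=10))
    b = data.draw(st.text(alphabet="ACGT", min_size=2, max_size=10))
    ref, query = _locus(a, atg=0), _locus(b, atg=0)
    aln = align_to_reference(query, ref)
    assert aln.score == pytest.approx(affine_optimum(a, b))


def test_empty_sequence_rejected():
    with pytest.raises(ValueError):
        LocusSequence("A", "g", "", 0, 0)


# ---------------------------------------------------------------------------
# position labels


def test_label_position_definition():
    locus = _locus("A" * 5000, atg=2000)
    assert label_position(2000, locus) == 1
    assert label_position(2001, locus) == 2  # the T of ATG
    assert label_position(1999, locus) == -1
    assert label_position(0, locus) == -2000
    with pytest.raises(IndexError):
        label_position(5000, locus)


@settings(max_examples=100, derandomize=True)
@given(offset=st.integers(min_value=0, max_value=4999))
def test_label_position_bijection(offset):
    locus = _locus("A" * 5000, atg=2000)
    pos = label_position(offset, locus)
    assert pos != 0
    assert position_to_offset(pos, locus) == offset


# ---------------------------------------------------------------------------
# region annotation


def test_annotate_region_cases():
    # 8-exon model whose 6th intron spans ATG-relative [+3200, +3400]
    bounds = [(1, 400), (501, 900), (1001, 1400), (1501, 1900), (2001, 2400),
              (2501, 3199), (3401, 3800), (3901, 4300)]
    exons = tuple((s + 5000, e + 5000) for s, e in bounds)
    model = GeneModel("g", "c", "+", 5001, 9300, exons)
    assert annotate_region(+3326, model) == "I6"
    assert annotate_region(-443, model) == "5U"
    assert annotate_region(+1, model) == "E1"
    assert annotate_region(+865, model) == "E2"
    assert annotate_region(model.genic_length + 10, model) == "3U"
    with pytest.raises(ValueError):
        annotate_region(0, model)


# ---------------------------------------------------------------------------
# variant calling


def test_identical_sequences_call_no_variants(rng):
    ref = random_locus(rng, 300)
    query = LocusSequence("Q", "g", ref.seq, ref.atg_offset, ref.stop_offset)
    assert call_variants(align_to_reference(query, ref), ref) == []


def test_planted_29bp_promoter_deletion_call():
    """A 29-bp deletion whose first deleted base sits 2022 bp 5' of the ATG
    is called as one DEL at position -2022 with size_delta -29."""
    from haplomark.synthetic_fixtures import PanelSpec, PlantedVariant, generate_panel

    spec = PanelSpec(
        seed=11,
        upstream=2200,  # the deletion starts just beyond the default 2-kb flank
        haplotype_profiles={"HapA": (), "HapB": (PlantedVariant(-2022, "DEL", length=29),)},
        accession_assignment={"ACC01": "HapB"},
        exon_lengths=(400, 300, 500),
        intron_lengths=(150, 250),
    )
    panel = generate_panel(spec)
    calls = call_variants(
        align_to_reference(panel.loci["ACC01"], panel.ref_locus),
        panel.ref_locus,
        panel.model,
    )
    assert len(calls) == 1
    v = calls[0]
    assert (v.position, v.vtype, v.size_delta, v.region) == (-2022, "DEL", -29, "5U")


def test_adjacent_del_ins_merges_to_sub():
    ref = _locus("AAAATTTTCCCCGGGGAAAA", acc="NIP", atg=0)
    # replace TTTTCCCC (8 bp) by GAG (3 bp)
    query = _locus("AAAAGAGGGGGAAAA", atg=0)
    calls = call_variants(align_to_reference(query, ref), ref)
    assert [v.vtype for v in calls] == ["SUB"]
    assert calls[0].size_delta == -5


def test_indels_left_aligned_in_repeats():
    ref = _locus("GATCTTTTTAGCATGCAAC", acc="NIP", atg=0)
    query = _locus("GATCTTTTAGCATGCAAC", atg=0)  # one T removed from the run
    calls = call_variants(align_to_reference(query, ref), ref)
    assert len(calls) == 1
    v = calls[0]
    # leftmost representation: first T of the run (offset 4 -> position +5)
    assert (v.vtype, v.position, v.ref_allele) == ("DEL", 5, "T")


# ---------------------------------------------------------------------------
# haplotype grouping


def _matrix(rows: dict[str, list[int]], variants=None):
    variants = variants or [
        Variant(-100, "SNP", "A", "C"),
        Variant(+50, "SNP", "G", "T"),
    ]
    calls = {
        acc: [v for v, g in zip(variants, row) if g] for acc, row in rows.items()
    }
    return build_matrix(calls, next(iter(rows)))


def test_all_identical_rows_form_single_hapa():
    m = _matrix({f"A{i}": [0, 0] for i in range(5)})
    haps = group_haplotypes(m, "A0")
    assert [h.name for h in haps.haplotypes] == ["HapA"]
    assert len(haps.haplotypes[0].members) == 5


def test_elite_profile_named_hapb():
    m = _matrix({"NIP": [0, 0], "A1": [1, 1], "A2": [1, 1]})
    profile = m.alt_keys("A1")
    haps = group_haplotypes(m, "NIP", elite_profile=profile)
    assert haps.get("HapA").members == ["NIP"]
    assert sorted(haps.get("HapB").members) == ["A1", "A2"]


def test_unmatched_elite_profile_reserved_with_warning():
    m = _matrix({"NIP": [0, 0], "A1": [1, 0]})
    with pytest.warns(UserWarning, match="HapB reserved"):
        haps = group_haplotypes(m, "NIP", elite_profile=frozenset({"nonexistent"}))
    assert haps.get("HapB").members == []


def test_remaining_haplotypes_ordered_by_size_then_member():
    rows = {"NIP": [0, 0], "B1": [1, 1], "C1": [1, 0], "C2": [1, 0], "D1": [0, 1]}
    m = _matrix(rows)
    haps = group_haplotypes(m, "NIP", elite_profile=m.alt_keys("B1"))
    assert haps.get("HapC").members == ["C1", "C2"]  # biggest non-elite group
    assert haps.get("HapD").members == ["D1"]


def test_haplotypes_partition_the_panel(panel):
    haps = panel.truth_haps
    seen: list[str] = []
    for hap in haps.haplotypes:
        seen.extend(hap.members)
    seen.extend(haps.nd_accessions)
    assert sorted(seen) == sorted(panel.truth_matrix.accessions)
    assert len(seen) == len(set(seen))


def test_flag_nd_rules(panel):
    m, haps = panel.truth_matrix, panel.truth_haps
    assert flag_nd("not-in-panel", m, haps)  # unextractable sequence
    assert not flag_nd("NIP", m, haps)  # identical to reference
    # an accession with 6 private variants against a 5-variant threshold
    private = [Variant(+401 + 60 * i, "SNP", "A", "C") for i in range(6)]
    m2 = build_matrix({"NIP": [], "ODD": private}, "NIP")
    haps2 = group_haplotypes(m2, "NIP", nd_accessions=["ODD"])
    assert flag_nd("ODD", m2, haps2, novel_threshold=5)
    assert not flag_nd("ODD", m2, haps2, novel_threshold=6)
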