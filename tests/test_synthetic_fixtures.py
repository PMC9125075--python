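import pytest

from haplomark.insilico_assay import assay
from haplomark.marker_design import patterns_distinguishable
from haplomark.synthetic_fixtures import (
    PanelSpec,
    PlantedVariant,
    default_panel_spec,
    generate_panel,
    ngr2_hapb_spec,
    random_panel_spec,
    synthesize_marker_templates,
    table2_fixture,
    table3_fixture,
    template_locus,
)
from haplomark.variant_haplotype import classify_panel


# ---------------------------------------------------------------------------
# panel generator


def test_generator_deterministic_under_seed():
    a = generate_panel(default_panel_spec(7))
    b = generate_panel(default_panel_spec(7))
    assert a.panel_fasta() == b.panel_fasta()
    assert list(a.truth_matrix.genotypes.columns) == list(b.truth_matrix.genotypes.columns)


def test_reference_carries_no_alt_alleles(panel):
    assert panel.truth_matrix.alt_keys("NIP") == frozenset()


def test_two_haplotype_panel_recovered_by_calling():
    spec = PanelSpec(
        seed=5,
        upstream=400, downstream=200,
        exon_lengths=(300, 250, 350), intron_lengths=(120, 180),
        haplotype_profiles={
            "HapA": (),
            "HapB": (PlantedVariant(-180, "INS", length=12),
                     PlantedVariant(+333, "SNP")),
        },
        accession_assignment={f"A{i}": ("HapB" if i % 2 else "HapA")
                              for i in range(1, 7)},
    )
    panel = generate_panel(spec)
    assert len(panel.loci) == 7  # reference + six assigned accessions
    matrix, haps = classify_panel(
        panel.loci, "NIP", panel.model,
        elite_profile=panel.truth_haps.get("HapB").profile,
    )
    assert set(matrix.genotypes.columns) == set(panel.truth_matrix.genotypes.columns)
    assert {h.name: sorted(h.members) for h in haps.haplotypes} == {
        h.name: sorted(h.members) for h in panel.truth_haps.haplotypes
    }


def test_overlapping_planted_variants_rejected():
    spec = PanelSpec(
        haplotype_profiles={
            "HapB": (PlantedVariant(-100, "DEL", length=30),
                     PlantedVariant(-90, "SNP")),
        },
        accession_assignment={"A1": "HapB"},
    )
    with pytest.raises(ValueError, match="overlap"):
        generate_panel(spec)


def test_ngr2_elite_snp_set_planted_at_published_positions():
    panel = generate_panel(ngr2_hapb_spec(2))
    truth = panel.truth_matrix
    assert len(truth.variants) == 14
    assert all(v.vtype == "SNP" for v in truth.variants)
    assert sorted(v.position for v in truth.variants) == sorted(
        [-1806, -1754, -1738, -1691, -1314, -935, -878, -844, -795,
         511, 641, 654, 2275, 3330]
    )


@pytest.mark.parametrize("seed", range(12))
def test_random_specs_round_trip(seed):
    panel = generate_panel(random_panel_spec(seed))
    ep = None
    if "HapB" in panel.truth_haps.named_profiles:
        ep = panel.truth_haps.get("HapB").profile
    matrix, haps = classify_panel(panel.loci, "NIP", panel.model, elite_profile=ep)
    assert set(matrix.genotypes.columns) == set(panel.truth_matrix.genotypes.columns)
    assert {h.name: sorted(h.members) for h in haps.haplotypes} == {
        h.name: sorted(h.members) for h in panel.truth_haps.haplotypes
    }


# ---------------------------------------------------------------------------
# transcribed fixtures


def test_table2_dimensions_and_reference_row(table2):
    assert len(table2.accessions) == 36
    assert table2.calls.shape == (36, 14)
    nip = table2.calls.loc["NIP"]
    # NIP is HapA for every gene except NGR2, where the source table keeps
    # the original study's class numbering (HapC) even for the reference
    assert (nip.drop("NGR2") == "HapA").all()
    assert nip["NGR2"] == "HapC"
    assert table2.printed_counts["NIP"] == 0


def test_table2_known_entries(table2):
    assert table2.calls.loc["N22", "SBM1"] == "HapB"
    assert table2.flagged.loc["N22", "SBM1"]
    assert table2.calls.loc["TM", "MYB61"] == "n.d."


def test_table3_census(table3):
    assert len(table3) == 18
    by_type = {}
    for m in table3:
        by_type[m.mtype] = by_type.get(m.mtype, 0) + 1
    assert by_type == {"Indel": 12, "CAPS": 3, "dCAPS": 1, "PARMS": 2}


def test_table3_known_records(table3):
    tcp19 = next(m for m in table3 if m.name == "TCP19 5U ID")
    assert tcp19.expected == {"ref": [231], "alt": [202]}  # 231 (-29)
    are1 = next(m for m in table3 if m.name == "ARE1 5U S")
    assert are1.enzyme.name == "DdeI"
    assert are1.expected["ref"] == [320] and are1.expected["alt"] == [100, 210]
    assert are1.target_haplotypes == ("HapC",)
    ngr5 = next(m for m in table3 if m.name == "NGR5 5U ID")
    assert ngr5.target_haplotypes == ("HapB", "HapC", "HapD")


# ---------------------------------------------------------------------------
# per-marker template loop


@pytest.mark.parametrize("idx", range(18))
def test_marker_templates_reproduce_encoded_patterns(table3, cfg, idx):
    marker = table3[idx]
    t_ref, t_alt = synthesize_marker_templates(marker, seed=42)
    band_ref = assay(template_locus("REF", marker.gene_id, t_ref), marker, cfg)
    band_alt = assay(template_locus("ALT", marker.gene_id, t_alt), marker, cfg)
    assert band_ref.call == "ref_class"
    assert band_alt.call == "alt_class"
    if marker.mtype != "PARMS":
        res = (cfg.gel_resolution_agarose if marker.mtype == "CAPS"
               else cfg.gel_resolution_page)
        assert not patterns_distinguishable(
            band_ref.fragments, list(marker.expected["ref"]), res)
        assert not patterns_distinguishable(
            band_alt.fragments, list(marker.expected["alt"]), res)
        # digestion conserves amplicon length on both allele classes
        from haplomark.insilico_assay import virtual_pcr

        for template, band in ((t_ref, band_ref), (t_alt, band_alt)):
            products = virtual_pcr(template, marker.binding_seq("F"),
                                   marker.binding_seq("R"))
            assert len(products) == 1
            assert sum(band.fragments) == len(products[0])
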