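"""Seeded synthetic panels and transcribed in-publication fixtures.

The panel generator emulates what the real workflow starts from: inbred
(homozygous) rice accessions whose gene-region sequences differ from the
reference accession by planted SNP/indel haplotype profiles over a locus
with a 2-kb upstream flank, an exon/intron gene body and a 1-kb downstream
flank.  Because the planted variants are known exactly, every downstream
stage (alignment, variant calling, haplotype grouping, marker design, assay
simulation) can be tested against generator truth without any downloads.

What the generator does NOT emulate: sequencing or assembly error,
heterozygosity, segmental duplications, or reference bias — so a green
round-trip shows the machinery is self-consistent, not that real genomes
would behave as cleanly.

The bundled panel matrix and marker set transcribed from the publication
live in version-controlled data files with provenance headers; code never
hard-codes their values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np

from .enzyme_kit import IUPAC, revcomp
from .locus_io import EnzymeCatalog, GeneModel, LocusSequence
from .marker_design import MarkerAssay, read_marker_table
from .scoring_report import HaplotypeTable, read_haplotype_table
from .variant_haplotype import (
    HaplotypeSet,
    Variant,
    VariantMatrix,
    annotate_region,
    build_matrix,
    group_haplotypes,
    position_to_offset,
)


# ---------------------------------------------------------------------------
# transcribed fixtures


def table2_fixture() -> HaplotypeTable:
    """The 36-accession x 14-gene haplotype matrix, with source-bold (elite)
    flags and the source's printed per-accession elite counts."""
    ref = resources.files("haplomark.data").joinpath("table2_haplotypes.tsv")
    with resources.as_file(ref) as path:
        return read_haplotype_table(path)


def table3_fixture(enzymes: EnzymeCatalog | None = None) -> list[MarkerAssay]:
    """The 18 transcribed marker assays (12 Indel, 3 CAPS, 1 dCAPS, 2 PARMS)."""
    ref = resources.files("haplomark.data").joinpath("table3_markers.tsv")
    with resources.as_file(ref) as path:
        return read_marker_table(path, enzymes)


# ---------------------------------------------------------------------------
# panel generator


@dataclass(frozen=True)
class PlantedVariant:
    """A variant to plant: position is signed ATG-relative (first affected
    reference base; insertions go immediately 5' of that base).

    For SNP give ``alt_seq`` (one base) or leave empty for an automatic
    transversion; DEL needs ``length``; INS needs ``alt_seq`` or ``length``
    (random fill); SUB needs both ``length`` (replaced reference bases) and
    ``alt_seq`` or ``alt_len``.
    """

    position: int
    vtype: str
    length: int = 0
    alt_seq: str = ""
    alt_len: int = 0


@dataclass
class PanelSpec:
    """Recipe for one synthetic gene-region panel.

    Defaults mirror the analysed-region definition (2-kb/1-kb flanks) and a
    mid-sized rice gene; ``base_gc`` approximates rice genic GC content.
    Planted variants must not overlap; indels additionally need >= 20 bp of
    clear flank so their aligned representation is unambiguous (SNP pairs
    may sit closer, as real haplotypes do).
    """

    seed: int = 0
    upstream: int = 2000
    downstream: int = 1000
    exon_lengths: tuple[int, ...] = (700, 450, 900)
    intron_lengths: tuple[int, ...] = (350, 550)
    base_gc: float = 0.44
    gene_id: str = "synthetic_gene"
    ref_accession: str = "NIP"
    haplotype_profiles: dict[str, tuple[PlantedVariant, ...]] = field(default_factory=dict)
    accession_assignment: dict[str, str] = field(default_factory=dict)
    elite_haplotype: str | None = "HapB"

    @property
    def genic_length(self) -> int:
        return sum(self.exon_lengths) + sum(self.intron_lengths)

    @property
    def locus_length(self) -> int:
        return self.upstream + self.genic_length + self.downstream


@dataclass
class SyntheticPanel:
    spec: PanelSpec
    model: GeneModel
    loci: dict[str, LocusSequence]
    truth_matrix: VariantMatrix
    truth_haps: HaplotypeSet

    @property
    def ref_locus(self) -> LocusSequence:
        return self.loci[self.spec.ref_accession]

    def panel_fasta(self) -> dict[str, str]:
        return {acc: locus.seq for acc, locus in self.loci.items()}


def _random_seq(rng: np.random.Generator, n: int, gc: float) -> str:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=n, p=probs))


def _build_model(spec: PanelSpec) -> GeneModel:
    exons = []
    pos = spec.upstream + 1  # 1-based genomic coordinate of the ATG
    for k, ex_len in enumerate(spec.exon_lengths):
        exons.append((pos, pos + ex_len - 1))
        pos += ex_len
        if k < len(spec.intron_lengths):
            pos += spec.intron_lengths[k]
    return GeneModel(
        gene_id=spec.gene_id,
        seq_id="synthetic",
        strand="+",
        atg_pos=spec.upstream + 1,
        stop_end=spec.upstream + spec.genic_length,
        exons=tuple(exons),
    )


def _validate_spacing(planted: list[tuple[int, PlantedVariant]]) -> None:
    """No overlaps anywhere; >= 20 bp clearance around indels."""
    spans = []
    for off, pv in planted:
        ref_len = {"SNP": 1, "INS": 0, "DEL": pv.length, "SUB": pv.length}[pv.vtype]
        spans.append((off, off + max(ref_len, 1) - 1, pv.vtype))
    spans.sort()
    for (s1, e1, t1), (s2, e2, t2) in zip(spans, spans[1:]):
        if s2 <= e1:
            raise ValueError(f"planted variants overlap at offsets {s1} and {s2}")
        if (t1 != "SNP" or t2 != "SNP") and s2 - e1 < 20:
            raise ValueError(
                f"indel variants need >= 20 bp clearance (offsets {s1}, {s2})"
            )


_TRANSVERSION = {"A": "C", "C": "A", "G": "T", "T": "G"}


def _resolve_variant(
    pv: PlantedVariant, ref_seq: list[str], off: int, rng: np.random.Generator,
    model: GeneModel,
) -> Variant:
    """Turn a planted recipe into a concrete left-aligned Variant, adjusting
    the reference context so the planted coordinates are already canonical."""
    if pv.vtype == "SNP":
        ref_base = ref_seq[off]
        alt = pv.alt_seq or _TRANSVERSION[ref_base]
        if alt == ref_base:
            raise ValueError(f"SNP at {pv.position:+d}: alt equals reference base")
        return Variant(pv.position, "SNP", ref_base, alt,
                       annotate_region(pv.position, model), 0)
    if pv.vtype == "DEL":
        if pv.length < 1:
            raise ValueError("DEL needs length >= 1")
        deleted = "".join(ref_seq[off:off + pv.length])
        # left-alignment guard: the base 5' of the run must differ from its tail
        if off > 0 and ref_seq[off - 1] == deleted[-1]:
            ref_seq[off - 1] = _TRANSVERSION[deleted[-1]]
        return Variant(pv.position, "DEL", deleted, "-",
                       annotate_region(pv.position, model), -pv.length)
    if pv.vtype == "INS":
        ins = pv.alt_seq or _random_seq(rng, pv.length or pv.alt_len, 0.5)
        if off > 0 and ins[-1] == ref_seq[off - 1]:
            ins = ins[:-1] + _TRANSVERSION[ref_seq[off - 1]]
        return Variant(pv.position, "INS", "-", ins,
                       annotate_region(pv.position, model), len(ins))
    if pv.vtype == "SUB":
        if pv.length < 1:
            raise ValueError("SUB needs length >= 1 (replaced reference bases)")
        replaced = "".join(ref_seq[off:off + pv.length])
        new = pv.alt_seq or _random_seq(rng, pv.alt_len, 0.5)
        if not new or len(new) == pv.length:
            raise ValueError("SUB needs an alt of a different, nonzero length")
        if new[0] == replaced[0]:
            new = _TRANSVERSION[replaced[0]] + new[1:]
        if new[-1] == replaced[-1]:
            new = new[:-1] + _TRANSVERSION[replaced[-1]]
        return Variant(pv.position, "SUB", replaced, new,
                       annotate_region(pv.position, model), len(new) - pv.length)
    raise ValueError(f"unknown planted variant type {pv.vtype!r}")


def generate_panel(spec: PanelSpec) -> SyntheticPanel:
    """Generate a panel deterministically from its spec.

    The reference accession carries no alt alleles; every other accession's
    sequence embodies exactly its assigned profile; a canonical ATG and stop
    codon are planted at the locus boundaries of the gene body.
    """
    rng = np.random.default_rng(spec.seed)
    model = _build_model(spec)
    ref_seq = list(_random_seq(rng, spec.locus_length, spec.base_gc))
    atg = spec.upstream
    ref_seq[atg:atg + 3] = list("ATG")
    stop = spec.upstream + spec.genic_length - 3
    ref_seq[stop:stop + 3] = list("TAA")

    ref_locus_probe = LocusSequence(  # offsets only; sequence refined below
        spec.ref_accession, spec.gene_id, "".join(ref_seq), atg,
        spec.upstream + spec.genic_length - 1,
    )
    profiles: dict[str, list[Variant]] = {}
    planted_offsets: list[tuple[int, PlantedVariant]] = []
    for name, recipe in spec.haplotype_profiles.items():
        for pv in recipe:
            planted_offsets.append((position_to_offset(pv.position, ref_locus_probe), pv))
    _validate_spacing(planted_offsets)
    protected = set(range(atg, atg + 3)) | set(range(stop, stop + 3))
    for off, pv in planted_offsets:
        span = range(off, off + max(pv.length, 1))
        if protected & set(span):
            raise ValueError(f"variant at {pv.position:+d} disturbs the ATG/stop codon")

    resolved_cache: dict[tuple, Variant] = {}
    for name, recipe in spec.haplotype_profiles.items():
        resolved = []
        for pv in recipe:
            key = (pv.position, pv.vtype, pv.length, pv.alt_seq, pv.alt_len)
            if key not in resolved_cache:
                off = position_to_offset(pv.position, ref_locus_probe)
                resolved_cache[key] = _resolve_variant(pv, ref_seq, off, rng, model)
            resolved.append(resolved_cache[key])
        profiles[name] = resolved
    profile_sets = [frozenset(v.key for v in vs) for vs in profiles.values()]
    if len(profile_sets) != len(set(profile_sets)):
        raise ValueError("haplotype profiles must be distinct")

    ref_str = "".join(ref_seq)
    ref_locus = LocusSequence(
        spec.ref_accession, spec.gene_id, ref_str, atg,
        spec.upstream + spec.genic_length - 1,
    )

    loci = {spec.ref_accession: ref_locus}
    calls: dict[str, list[Variant]] = {spec.ref_accession: []}
    for accession, hap_name in spec.accession_assignment.items():
        if accession == spec.ref_accession:
            continue
        variants = profiles.get(hap_name)
        if variants is None:
            raise KeyError(f"{accession}: unknown haplotype {hap_name!r}")
        seq = ref_str
        atg_shift = 0
        genic_shift = 0
        for v in sorted(variants, key=lambda v: -position_to_offset(v.position, ref_locus)):
            off = position_to_offset(v.position, ref_locus)
            if v.vtype == "SNP":
                seq = seq[:off] + v.alt_allele + seq[off + 1:]
            elif v.vtype == "DEL":
                seq = seq[:off] + seq[off + len(v.ref_allele):]
            elif v.vtype == "INS":
                seq = seq[:off] + v.alt_allele + seq[off:]
            else:  # SUB
                seq = seq[:off] + v.alt_allele + seq[off + len(v.ref_allele):]
            if off < atg:
                atg_shift += v.size_delta
            elif off <= ref_locus.stop_offset:
                genic_shift += v.size_delta
        loci[accession] = LocusSequence(
            accession, spec.gene_id, seq, atg + atg_shift,
            ref_locus.stop_offset + atg_shift + genic_shift,
        )
        calls[accession] = list(variants)

    matrix = build_matrix(calls, spec.ref_accession)
    elite_profile = None
    if spec.elite_haplotype and spec.elite_haplotype in profiles:
        elite_profile = frozenset(v.key for v in profiles[spec.elite_haplotype])
    haps = group_haplotypes(matrix, spec.ref_accession, elite_profile, spec.gene_id)
    return SyntheticPanel(spec, model, loci, matrix, haps)


def default_panel_spec(seed: int = 0) -> PanelSpec:
    """A 20-accession panel over the default ~6.3-kb locus: an elite HapB
    (one 20-bp promoter insertion plus three SNPs) carried by 8 accessions,
    a HapC differing by two SNPs, and reference-like accessions."""
    hapb = (
        PlantedVariant(-1197, "INS", length=20),
        PlantedVariant(-935, "SNP"),
        PlantedVariant(+511, "SNP"),
        PlantedVariant(+1701, "SNP"),
    )
    hapc = (
        PlantedVariant(-443, "SNP"),
        PlantedVariant(+865, "SNP"),
    )
    accs_b = [f"XI{i:02d}" for i in range(1, 9)]
    accs_c = [f"GJ{i:02d}" for i in range(1, 5)]
    accs_a = [f"REF{i:02d}" for i in range(1, 8)]
    assignment = {a: "HapB" for a in accs_b}
    assignment |= {a: "HapC" for a in accs_c}
    assignment |= {a: "HapA" for a in accs_a}
    return PanelSpec(
        seed=seed,
        haplotype_profiles={"HapA": (), "HapB": hapb, "HapC": hapc},
        accession_assignment=assignment,
    )


def random_panel_spec(seed: int, compact: bool = True) -> PanelSpec:
    """A randomized recovery-test spec: 2-4 haplotypes with random SNP/indel
    profiles.  ``compact`` shrinks the locus (~1.3 kb) so that large seeded
    batches align quickly; the variant logic is size-independent."""
    rng = np.random.default_rng(seed)
    if compact:
        spec_kw = dict(upstream=300, downstream=150,
                       exon_lengths=(220, 160, 260), intron_lengths=(90, 130))
    else:
        spec_kw = {}
    base = PanelSpec(seed=seed, **spec_kw)
    lo = -base.upstream + 25
    hi = base.genic_length + base.downstream - 25
    n_haps = int(rng.integers(2, 5))
    # keep planted variants clear of the ATG and stop codons
    taken: list[int] = [base.upstream + 1, base.upstream + base.genic_length - 2]
    profiles: dict[str, tuple[PlantedVariant, ...]] = {"HapA": ()}
    for h in range(1, n_haps):
        n_var = int(rng.integers(1, 5))
        recipe = []
        for _ in range(n_var):
            for _attempt in range(100):
                pos = int(rng.integers(lo, hi))
                if pos == 0:
                    continue
                off = base.upstream + (pos - 1 if pos > 0 else pos)
                if all(abs(off - t) >= 60 for t in taken):
                    break
            else:
                continue
            taken.append(off)
            vtype = str(rng.choice(["SNP", "SNP", "INS", "DEL"]))
            if vtype == "SNP":
                recipe.append(PlantedVariant(pos, "SNP"))
            elif vtype == "INS":
                recipe.append(PlantedVariant(pos, "INS", length=int(rng.integers(2, 31))))
            else:
                recipe.append(PlantedVariant(pos, "DEL", length=int(rng.integers(2, 31))))
        if recipe:
            profiles[f"Hap{chr(ord('A') + h)}"] = tuple(recipe)
    assignment = {}
    i = 1
    for name in profiles:
        for _ in range(int(rng.integers(1, 3))):
            assignment[f"ACC{i:02d}"] = name
            i += 1
    elite = "HapB" if "HapB" in profiles else None
    return PanelSpec(
        seed=seed + 1, haplotype_profiles=profiles,
        accession_assignment=assignment, elite_haplotype=elite, **spec_kw,
    )


def ngr2_hapb_spec(seed: int = 0) -> PanelSpec:
    """Panel planting the NGR2 elite-haplotype SNP set at its 14 published
    ATG-relative positions over a gene body long enough to hold them."""
    positions = [-1806, -1754, -1738, -1691, -1314, -935, -878, -844, -795,
                 +511, +641, +654, +2275, +3330]
    hapb = tuple(PlantedVariant(p, "SNP") for p in positions)
    return PanelSpec(
        seed=seed,
        gene_id="NGR2",
        exon_lengths=(600, 500, 700, 1000),
        intron_lengths=(300, 200, 400),
        haplotype_profiles={"HapA": (), "HapB": hapb},
        accession_assignment={"ACC01": "HapB", "ACC02": "HapB", "ACC03": "HapA"},
    )


# ---------------------------------------------------------------------------
# per-marker template synthesis (internal-consistency loop)


def _concretize(recognition: str) -> str:
    return "".join(IUPAC[c][0] for c in recognition)


def _site_breaker(recognition: str) -> tuple[int, str]:
    """A position in the recognition site and a base that breaks it there."""
    for i, code in enumerate(recognition):
        allowed = IUPAC[code]
        if len(allowed) < 4:
            breaker = next(b for b in "ACGT" if b not in allowed)
            return i, breaker
    raise ValueError(f"recognition {recognition} cannot be broken by one base")


def _clean_filler(rng: np.random.Generator, n: int, forbidden: list[str]) -> str:
    for _ in range(200):
        cand = _random_seq(rng, n, 0.5)
        if not any(f in cand for f in forbidden if f):
            return cand
    raise RuntimeError("could not sample filler avoiding forbidden motifs")


def synthesize_marker_templates(
    marker: MarkerAssay, seed: int = 0, flank: int = 40
) -> tuple[str, str]:
    """Build (reference-class, elite-class) locus templates that embody a
    marker's own specification: primer sites at the implied spacing, and the
    planted indel / restriction site / allele base the encoding describes.

    This closes the design/assay loop for transcribed markers — it validates
    the simulation engine against the encoded read-outs, not the original
    genomes (which the publication does not deposit).
    """
    rng = np.random.default_rng(seed)
    mtype = marker.mtype

    if mtype == "Indel":
        fwd = marker.binding_seq("F")
        rev = marker.binding_seq("R")
        rev_rc = revcomp(rev)
        ref_len = marker.expected["ref"][0]
        delta = marker.expected["alt"][0] - ref_len
        interior = ref_len - len(fwd) - len(rev)
        if interior < max(0, -delta) + 2:
            raise ValueError(f"{marker.name}: encoded amplicon too short to synthesize")
        for attempt in range(100):
            mid = _clean_filler(rng, interior, [fwd, rev_rc])
            if delta >= 0:
                cut = interior // 2
                ins = _clean_filler(rng, delta, [fwd, rev_rc]) if delta else ""
                mid_alt = mid[:cut] + ins + mid[cut:]
            else:
                cut = (interior + delta) // 2  # deletion must fit the interior
                mid_alt = mid[:cut] + mid[cut - delta:]
            amp_ref = fwd + mid + rev_rc
            amp_alt = fwd + mid_alt + rev_rc
            t_ref = _flanked(rng, amp_ref, flank, [fwd, rev_rc])
            t_alt = _flanked(rng, amp_alt, flank, [fwd, rev_rc])
            if _amplifies_uniquely(t_ref, fwd, rev) and _amplifies_uniquely(t_alt, fwd, rev):
                return t_ref, t_alt
        raise RuntimeError(f"{marker.name}: template synthesis did not converge")

    if mtype == "CAPS":
        return _synthesize_caps(marker, rng, flank)
    if mtype == "dCAPS":
        return _synthesize_dcaps(marker, rng, flank)
    if mtype == "PARMS":
        return _synthesize_parms(marker, rng, flank)
    raise ValueError(f"unknown marker type {mtype}")


def _flanked(rng: np.random.Generator, amp: str, flank: int, forbidden: list[str]) -> str:
    return (_clean_filler(rng, flank, forbidden) + amp
            + _clean_filler(rng, flank, forbidden))


def _amplifies_uniquely(template: str, fwd: str, rev: str) -> bool:
    from .insilico_assay import virtual_pcr

    return len(virtual_pcr(template, fwd, rev)) == 1


def _synthesize_caps(marker: MarkerAssay, rng: np.random.Generator, flank: int):
    from .enzyme_kit import digest, find_sites

    fwd = marker.binding_seq("F")
    rev = marker.binding_seq("R")
    rev_rc = revcomp(rev)
    enzyme = marker.enzyme
    ref_frags, alt_frags = marker.expected["ref"], marker.expected["alt"]
    cut_class, cut_frags, uncut_len = (
        ("ref", ref_frags, alt_frags[0]) if len(ref_frags) > 1
        else ("alt", alt_frags, ref_frags[0])
    )
    amp_len = uncut_len
    site = _concretize(enzyme.recognition)
    cut_at = cut_frags[0]
    site_start = cut_at - enzyme.cut_offset
    if not (len(fwd) <= site_start and site_start + len(site) <= amp_len - len(rev)):
        raise ValueError(f"{marker.name}: encoded cut position clashes with primers")
    break_idx, breaker = _site_breaker(enzyme.recognition)
    for attempt in range(200):
        mid = _clean_filler(rng, amp_len - len(fwd) - len(rev), [fwd, rev_rc])
        amp_cut = fwd + mid + rev_rc
        amp_cut = amp_cut[:site_start] + site + amp_cut[site_start + len(site):]
        amp_uncut = (amp_cut[:site_start + break_idx] + breaker
                     + amp_cut[site_start + break_idx + 1:])
        if len(find_sites(amp_cut, enzyme)) != 1 or find_sites(amp_uncut, enzyme):
            continue
        realized = digest(amp_cut, enzyme)
        if len(realized) != len(cut_frags):
            continue
        amp_ref, amp_alt = (
            (amp_cut, amp_uncut) if cut_class == "ref" else (amp_uncut, amp_cut)
        )
        t_ref = _flanked(rng, amp_ref, flank, [fwd, rev_rc])
        t_alt = _flanked(rng, amp_alt, flank, [fwd, rev_rc])
        if (_amplifies_uniquely(t_ref, fwd, rev)
                and _amplifies_uniquely(t_alt, fwd, rev)
                and not find_sites(t_ref[:flank], enzyme)
                and not find_sites(t_ref[-flank:], enzyme)):
            return t_ref, t_alt
    raise RuntimeError(f"{marker.name}: CAPS template synthesis did not converge")


def _synthesize_dcaps(marker: MarkerAssay, rng: np.random.Generator, flank: int):
    from .enzyme_kit import find_sites

    primer = marker.primers["F"]  # engineered base lowercase
    engineered = marker.engineered_positions("F")
    if len(engineered) != 1:
        raise ValueError(f"{marker.name}: expected exactly one engineered base")
    idx, eng_base = engineered[0]
    fwd = marker.binding_seq("F")
    rev = marker.binding_seq("R")
    rev_rc = revcomp(rev)
    enzyme = marker.enzyme
    ref_frags, alt_frags = marker.expected["ref"], marker.expected["alt"]
    cut_class = "ref" if len(ref_frags) > 1 else "alt"
    amp_len = (alt_frags if cut_class == "ref" else ref_frags)[0]
    # genomic base under the engineered position differs from the primer
    genomic_sub = "A" if eng_base != "A" else "G"
    fwd_genomic = fwd[:idx] + genomic_sub + fwd[idx + 1:]
    # the template base right after the primer completes the site for the
    # cut class; any non-matching base breaks it for the other class
    m = enzyme.site_len()
    # find the site placement implied by the primer's engineered suffix
    placement = None
    for w in range(max(0, len(fwd) - m + 1), len(fwd)):
        window = fwd + "N" * m
        need = enzyme.recognition
        ok = all(
            window[w + i] == "N" or window[w + i] in IUPAC[need[i]]
            for i in range(m)
        )
        if ok and w <= idx < w + m:
            placement = w
            break
    if placement is None:
        raise ValueError(f"{marker.name}: engineered primer completes no site")
    tail_len = placement + m - len(fwd)  # template bases completing the site
    completing = _concretize(enzyme.recognition)[m - tail_len:]
    break_idx, breaker = _site_breaker(enzyme.recognition[m - tail_len:])
    completing_broken = (completing[:break_idx] + breaker + completing[break_idx + 1:])
    for attempt in range(200):
        interior = amp_len - len(fwd) - tail_len - len(rev)
        mid = _clean_filler(rng, interior, [fwd, rev_rc])
        body_cut = completing + mid + rev_rc
        body_uncut = completing_broken + mid + rev_rc
        t_cut = fwd_genomic + body_cut
        t_uncut = fwd_genomic + body_uncut
        amp_cut = fwd + body_cut
        amp_uncut = fwd + body_uncut
        if len(find_sites(amp_cut, enzyme)) != 1 or find_sites(amp_uncut, enzyme):
            continue
        t_ref_core, t_alt_core = (
            (t_cut, t_uncut) if cut_class == "ref" else (t_uncut, t_cut)
        )
        t_ref = _flanked(rng, t_ref_core, flank, [fwd, rev_rc])
        t_alt = _flanked(rng, t_alt_core, flank, [fwd, rev_rc])
        if _amplifies_uniquely(t_ref, fwd, rev) and _amplifies_uniquely(t_alt, fwd, rev):
            return t_ref, t_alt
    raise RuntimeError(f"{marker.name}: dCAPS template synthesis did not converge")


def _synthesize_parms(marker: MarkerAssay, rng: np.random.Generator, flank: int):
    core_ref = marker.binding_seq("FC")
    core_alt = marker.binding_seq("FT")
    rev = marker.binding_seq("R")
    rev_rc = revcomp(rev)
    amp_core = 150 - len(core_ref) - len(rev)
    for attempt in range(100):
        mid = _clean_filler(rng, amp_core, [core_ref, core_alt, rev_rc])
        t_ref = _flanked(rng, core_ref + mid + rev_rc, flank,
                         [core_ref, core_alt, rev_rc])
        t_alt = t_ref.replace(core_ref + mid, core_alt + mid)
        if (_amplifies_uniquely(t_ref, core_ref, rev)
                and _amplifies_uniquely(t_alt, core_alt, rev)):
            return t_ref, t_alt
    raise RuntimeError(f"{marker.name}: PARMS template synthesis did not converge")


def template_locus(accession: str, gene_id: str, template: str) -> LocusSequence:
    """Wrap a synthesized marker template as a minimal locus (no real gene
    body; offsets are placeholders for assay simulation only)."""
    return LocusSequence(accession, gene_id, template, 0, len(template) - 1)
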