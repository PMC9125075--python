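"""Virtual genotyping: PCR, digestion, band resolution and PARMS calls.

The primer-binding model is a deliberate simplification of thermodynamic
annealing: a primer binds where its 3'-terminal base matches the template
exactly and at most one other base mismatches.  This keeps engineered dCAPS
primers binding (their mismatch is internal) while making PARMS
allele-specific primers refractory on the wrong allele (their mismatch is
terminal).  Amplicons incorporate the primer sequences, as real PCR products
do — which is what turns a dCAPS primer's engineered base into a restriction
site in the product.

The gel model calls two fragments distinguishable when they differ by at
least the resolution threshold: 4 bp on the polyacrylamide gels used for
Indel and dCAPS products, 20 bp on the agarose gels used for CAPS products.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .enzyme_kit import digest, revcomp
from .locus_io import LocusSequence
from .marker_design import DesignConfig, MarkerAssay, patterns_distinguishable
from .variant_haplotype import HaplotypeSet


@dataclass(frozen=True)
class BindingParams:
    max_mismatch: int = 1
    max_product: int = 5000


@dataclass
class BandPattern:
    """One accession's read-out for one marker.

    ``fragments`` is empty when nothing amplified (null allele); for
    CAPS/dCAPS the fragments sum to the accession's amplicon length.
    """

    marker: str
    accession: str
    fragments: list[int]
    call: str  # ref_class | alt_class | ambiguous | null

    def __post_init__(self) -> None:
        if self.call not in ("ref_class", "alt_class", "ambiguous", "null"):
            raise ValueError(f"unknown call {self.call!r}")
        if self.call != "null" and not self.fragments:
            raise ValueError("a non-null call needs at least one fragment")


def _binding_sites(template: str, primer: str, params: BindingParams) -> list[int]:
    """Start offsets where the primer's 3' base matches exactly and the rest
    mismatches at most ``max_mismatch`` bases."""
    primer = primer.upper()
    L = len(primer)
    hits = []
    for i in range(len(template) - L + 1):
        window = template[i:i + L]
        if window[-1] != primer[-1]:
            continue
        mismatches = sum(a != b for a, b in zip(window[:-1], primer[:-1]))
        if mismatches <= params.max_mismatch:
            hits.append(i)
    return hits


def virtual_pcr(
    template: str,
    fwd: str,
    rev: str,
    binding: BindingParams = BindingParams(),
) -> list[str]:
    """Predicted PCR products, 5'->3' on the template's top strand.

    Every forward site on the plus strand pairs with the nearest downstream
    reverse site within the maximum product length.  Products incorporate
    the primer sequences at their ends.
    """
    if not fwd or not rev:
        raise ValueError("primers must be nonempty")
    template = template.upper()
    fwd, rev = fwd.upper(), rev.upper()
    rev_rc = revcomp(rev)
    fwd_sites = _binding_sites(template, fwd, binding)
    # reverse primer binds the minus strand; on the top strand its footprint
    # reads as revcomp(rev), whose FIRST base is the primer's 3' terminus
    Lr = len(rev)
    rev_sites = [
        j for j in range(len(template) - Lr + 1)
        if template[j] == rev_rc[0]
        and sum(a != b for a, b in zip(template[j + 1:j + Lr], rev_rc[1:]))
        <= binding.max_mismatch
    ]
    products = []
    for i in fwd_sites:
        downstream = [j for j in rev_sites
                      if j >= i + len(fwd) and j + Lr - i <= binding.max_product]
        if not downstream:
            continue
        j = min(downstream)
        middle = template[i + len(fwd):j]
        products.append(fwd + middle + rev_rc)
    return products


def _pattern_matches(frags: list[int], expected: list[int], resolution: int) -> bool:
    return not patterns_distinguishable(frags, expected, resolution)


def marker_resolution(marker: MarkerAssay, cfg: DesignConfig) -> int:
    """Gel resolution applicable to a marker's products (PAGE vs agarose)."""
    return (cfg.gel_resolution_agarose if marker.mtype == "CAPS"
            else cfg.gel_resolution_page)


def assay(
    locus: LocusSequence,
    marker: MarkerAssay,
    cfg: DesignConfig = DesignConfig(),
    binding: BindingParams | None = None,
) -> BandPattern:
    """Simulate one marker on one accession locus and call the allele class."""
    if marker.gene_id != locus.gene_id:
        raise ValueError(f"marker {marker.name} is for {marker.gene_id}, "
                         f"locus is {locus.gene_id}")
    binding = binding or BindingParams(max_mismatch=cfg.pcr_max_mismatch,
                                       max_product=cfg.pcr_max_product)
    template = locus.seq

    if marker.mtype == "PARMS":
        products = {
            role: virtual_pcr(template, marker.binding_seq(role),
                              marker.binding_seq("R"), binding)
            for role in ("FC", "FT")
        }
        amplified = [role for role, prods in products.items() if prods]
        if not amplified:
            return BandPattern(marker.name, locus.accession, [], "null")
        if len(amplified) == 2:
            frags = [len(products["FC"][0])]
            return BandPattern(marker.name, locus.accession, frags, "ambiguous")
        role = amplified[0]
        call = "ref_class" if role == "FC" else "alt_class"
        return BandPattern(marker.name, locus.accession,
                           [len(products[role][0])], call)

    products = virtual_pcr(template, marker.binding_seq("F"),
                           marker.binding_seq("R"), binding)
    if not products:
        return BandPattern(marker.name, locus.accession, [], "null")
    if len(products) > 1:
        return BandPattern(marker.name, locus.accession,
                           [len(p) for p in products], "ambiguous")
    product = products[0]
    resolution = marker_resolution(marker, cfg)

    if marker.mtype == "Indel":
        frags = [len(product)]
    else:
        frags = digest(product, marker.enzyme)

    ref_hit = _pattern_matches(frags, marker.expected["ref"], resolution)
    alt_hit = _pattern_matches(frags, marker.expected["alt"], resolution)
    if ref_hit and not alt_hit:
        call = "ref_class"
    elif alt_hit and not ref_hit:
        call = "alt_class"
    else:
        call = "ambiguous"
    return BandPattern(marker.name, locus.accession, frags, call)


@dataclass
class ValidationRow:
    accession: str
    pattern: BandPattern
    expected_call: str | None  # None for n.d. accessions
    concordant: bool | None


@dataclass
class ValidationReport:
    marker: str
    rows: list[ValidationRow] = field(default_factory=list)
    passed: bool = False
    reasons: list[str] = field(default_factory=list)

    @property
    def n_alt(self) -> int:
        return sum(1 for r in self.rows if r.pattern.call == "alt_class")

    @property
    def n_ref(self) -> int:
        return sum(1 for r in self.rows if r.pattern.call == "ref_class")


def validate_marker(
    marker: MarkerAssay,
    panel: dict[str, LocusSequence],
    truth: HaplotypeSet,
    cfg: DesignConfig = DesignConfig(),
) -> ValidationReport:
    """Check a marker's discriminating power against a panel with known
    haplotypes: target-haplotype members must call alt_class, every other
    named accession ref_class, and the two expected patterns must be
    separated at the applicable gel resolution."""
    report = ValidationReport(marker=marker.name)
    if marker.mtype != "PARMS":
        resolution = marker_resolution(marker, cfg)
        if not patterns_distinguishable(
            list(marker.expected["ref"]), list(marker.expected["alt"]), resolution
        ):
            report.reasons.append(
                f"unresolvable: allele patterns closer than {resolution} bp"
            )
    for accession, locus in panel.items():
        pattern = assay(locus, marker, cfg)
        hap = truth.name_of(accession)
        if hap == "n.d.":
            report.rows.append(ValidationRow(accession, pattern, None, None))
            continue
        expected = "alt_class" if hap in marker.target_haplotypes else "ref_class"
        report.rows.append(
            ValidationRow(accession, pattern, expected, pattern.call == expected)
        )
    discordant = [r.accession for r in report.rows if r.concordant is False]
    if discordant:
        report.reasons.append(f"discordant calls: {', '.join(discordant)}")
    report.passed = not report.reasons
    return report
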