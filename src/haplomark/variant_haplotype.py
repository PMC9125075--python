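"""Variant calling and haplotype classification over gene-region alignments.

Each accession locus is globally aligned to the reference accession with
affine gap penalties, differences are reported as SNP/INS/DEL/SUB variants at
signed ATG-relative positions (+1 = the A of ATG, -1 = the base immediately
5' of it; there is no position 0), and accessions sharing an identical
variant profile are grouped into named haplotypes: the reference accession's
profile is HapA, the designated elite profile is HapB, and the rest are
HapC, HapD, ... by descending member count.

Panel accessions are assumed to be inbred (homozygous) lines, so a genotype
is simply ref/alt per variant; there is no heterozygote model.  Global
alignment is practical up to roughly 20-kb loci at desk scale; variants from
larger structural differences should be supplied through the variant-table
input path instead.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd
from Bio import Align

from .locus_io import GeneModel, LocusSequence

GAP = "-"


# ---------------------------------------------------------------------------
# positions and regions


def label_position(locus_offset: int, locus: LocusSequence) -> int:
    """Signed ATG-relative position of a 0-based locus offset (never 0)."""
    if not 0 <= locus_offset < len(locus.seq):
        raise IndexError(f"offset {locus_offset} outside locus of length {len(locus.seq)}")
    rel = locus_offset - locus.atg_offset
    return rel + 1 if rel >= 0 else rel


def position_to_offset(position: int, locus: LocusSequence) -> int:
    """Inverse of :func:`label_position`."""
    if position == 0:
        raise ValueError("ATG-relative convention has no position 0")
    offset = locus.atg_offset + (position - 1 if position > 0 else position)
    if not 0 <= offset < len(locus.seq):
        raise IndexError(f"position {position:+d} outside locus")
    return offset


def annotate_region(position: int, model: GeneModel) -> str:
    """Map a signed ATG-relative position to ``5U``, ``E<k>``, ``I<k>`` or ``3U``.

    Everything 5' of the ATG is called 5U and everything 3' of the stop codon
    3U, regardless of transcript structure, mirroring the fixed-flank region
    definition; genic positions get their exon/intron ordinal in
    transcription order.
    """
    if position == 0:
        raise ValueError("ATG-relative convention has no position 0")
    if position < 0:
        return "5U"
    stop_rel = model.genic_length  # ATG-relative position of the last stop base
    if position > stop_rel:
        return "3U"
    rel_exons = model.exons_atg_relative()
    for k, (s, e) in enumerate(rel_exons, 1):
        if s <= position <= e:
            return f"E{k}"
        if k < len(rel_exons) and e < position < rel_exons[k][0]:
            return f"I{k}"
    raise ValueError(f"position {position:+d} not covered by the gene model")


# ---------------------------------------------------------------------------
# variants


@dataclass(frozen=True)
class Variant:
    """One sequence difference against the reference accession.

    ``position`` is the signed ATG-relative position of the first affected
    reference base (for insertions, the reference base immediately 3' of the
    insertion point).  ``SUB`` is a replacement, e.g. a 637-bp stretch
    replaced by 12 bp.  Indels are left-aligned in repeat tracts.
    """

    position: int
    vtype: str
    ref_allele: str
    alt_allele: str
    region: str = ""
    size_delta: int = 0

    def __post_init__(self) -> None:
        if self.position == 0:
            raise ValueError("no position 0 in the ATG-relative convention")
        if self.vtype not in ("SNP", "INS", "DEL", "SUB"):
            raise ValueError(f"unknown variant type {self.vtype!r}")
        if self.vtype == "SNP" and not (
            len(self.ref_allele) == len(self.alt_allele) == 1 and self.size_delta == 0
        ):
            raise ValueError("SNP must have single-base alleles and size_delta 0")
        if self.vtype == "INS" and self.ref_allele != GAP:
            raise ValueError("INS must have ref allele '-'")
        if self.vtype == "DEL" and self.alt_allele != GAP:
            raise ValueError("DEL must have alt allele '-'")

    @property
    def key(self) -> str:
        return f"{self.position:+d}:{self.vtype}:{self.ref_allele}>{self.alt_allele}"

    @property
    def has_ambiguous_allele(self) -> bool:
        return any(b not in "ACGT-" for b in self.ref_allele + self.alt_allele)


def _make_variant(position: int, vtype: str, ref: str, alt: str,
                  model: GeneModel | None) -> Variant:
    delta = (0 if vtype == "SNP"
             else (len(alt) if alt != GAP else 0) - (len(ref) if ref != GAP else 0))
    region = annotate_region(position, model) if model is not None else ""
    return Variant(position, vtype, ref, alt, region, delta)


# ---------------------------------------------------------------------------
# alignment


@dataclass(frozen=True)
class AlignParams:
    """Affine-gap scoring; a gap of length k costs ``gap_open + k*gap_extend``.

    The defaults favour one long contiguous Indel over fragmented gaps,
    which matches how gene-region Indels present (e.g. a single 520-bp
    deletion rather than scattered short gaps).
    """

    match: float = 2.0
    mismatch: float = -3.0
    gap_open: float = -5.0
    gap_extend: float = -2.0


@dataclass(frozen=True)
class PairAlignment:
    """A global alignment as two gapped rows plus its score."""

    ref_row: str
    query_row: str
    score: float

    def __post_init__(self) -> None:
        if len(self.ref_row) != len(self.query_row):
            raise ValueError("alignment rows differ in length")


def align_to_reference(
    query: LocusSequence, ref: LocusSequence, params: AlignParams = AlignParams()
) -> PairAlignment:
    """Global affine-gap alignment of a query locus to the reference locus.

    Deterministic: among co-optimal alignments the aligner's first traceback
    is always taken.
    """
    if query.gene_id != ref.gene_id:
        raise ValueError(f"gene mismatch: {query.gene_id} vs {ref.gene_id}")
    if not query.seq or not ref.seq:
        raise ValueError("cannot align empty sequences")
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = params.match
    aligner.mismatch_score = params.mismatch
    # PairwiseAligner charges open on the first gap base, so fold one extend in
    aligner.open_gap_score = params.gap_open + params.gap_extend
    aligner.extend_gap_score = params.gap_extend
    aln = aligner.align(ref.seq, query.seq)[0]
    return PairAlignment(ref_row=str(aln[0]), query_row=str(aln[1]), score=aln.score)


def call_variants(
    alignment: PairAlignment, ref: LocusSequence, model: GeneModel | None = None
) -> list[Variant]:
    """Turn an alignment into left-aligned SNP/INS/DEL/SUB variants.

    Adjacent gap columns merge into one INS/DEL; an adjacent deletion +
    insertion pair merges into a SUB; positions are ATG-relative at the
    first affected reference base.
    """
    events: list[tuple[int, str, str]] = []  # (ref offset, ref seg, alt seg)
    ref_pos = 0
    cur: tuple[int, str, str] | None = None
    for r, q in zip(alignment.ref_row, alignment.query_row):
        if r != GAP and q != GAP and r == q:
            if cur is not None:
                events.append(cur)
                cur = None
            ref_pos += 1
            continue
        if cur is None:
            cur = (ref_pos, "", "")
        off, rs, qs = cur
        cur = (off, rs + (r if r != GAP else ""), qs + (q if q != GAP else ""))
        if r != GAP:
            ref_pos += 1
    if cur is not None:
        events.append(cur)

    variants: list[Variant] = []
    refseq = ref.seq
    for off, rs, qs in events:
        if rs and qs and len(rs) == len(qs) == 1:
            variants.append(_make_variant(label_position(off, ref), "SNP", rs, qs, model))
        elif rs and qs:
            # mismatch runs decompose into per-base SNPs; unequal runs are SUBs
            if len(rs) == len(qs) and all(a != b for a, b in zip(rs, qs)):
                for i, (a, b) in enumerate(zip(rs, qs)):
                    variants.append(
                        _make_variant(label_position(off + i, ref), "SNP", a, b, model)
                    )
            else:
                variants.append(_make_variant(label_position(off, ref), "SUB", rs, qs, model))
        elif rs:  # deletion in query
            while off > 0 and refseq[off - 1] == rs[-1]:
                off -= 1
                rs = refseq[off] + rs[:-1]
            variants.append(_make_variant(label_position(off, ref), "DEL", rs, GAP, model))
        else:  # insertion in query
            while off > 0 and refseq[off - 1] == qs[-1]:
                off -= 1
                qs = refseq[off] + qs[:-1]
            anchor = min(off, len(refseq) - 1)
            variants.append(_make_variant(label_position(anchor, ref), "INS", GAP, qs, model))
    variants.sort(key=lambda v: (v.position if v.position < 0 else v.position - 1, v.vtype))
    return variants


# ---------------------------------------------------------------------------
# matrices and haplotypes


@dataclass
class VariantMatrix:
    """Accession x variant genotype table for an inbred panel.

    Genotype codes: 0 = reference allele, 1 = alternate allele, -1 = missing.
    """

    variants: list[Variant]
    genotypes: pd.DataFrame

    def __post_init__(self) -> None:
        keys = [v.key for v in self.variants]
        if list(self.genotypes.columns) != keys:
            raise ValueError("genotype columns must match variant keys, in order")
        if not self.genotypes.isin([0, 1, -1]).all().all():
            raise ValueError("inbred panel: genotypes must be 0/1/-1 (no heterozygotes)")

    @property
    def accessions(self) -> list[str]:
        return list(self.genotypes.index)

    def variant_by_key(self, key: str) -> Variant:
        for v in self.variants:
            if v.key == key:
                return v
        raise KeyError(key)

    def alt_keys(self, accession: str) -> frozenset[str]:
        row = self.genotypes.loc[accession]
        return frozenset(row.index[row == 1])


def build_matrix(calls: dict[str, list[Variant]], ref_accession: str) -> VariantMatrix:
    """Assemble per-accession variant calls into a matrix.

    The reference accession carries the reference allele everywhere by
    definition; it is added even when absent from ``calls``.
    """
    union: dict[str, Variant] = {}
    for acc_variants in calls.values():
        for v in acc_variants:
            union.setdefault(v.key, v)
    variants = sorted(
        union.values(), key=lambda v: (v.position if v.position < 0 else v.position - 1, v.key)
    )
    keys = [v.key for v in variants]
    accessions = list(calls)
    if ref_accession not in accessions:
        accessions.insert(0, ref_accession)
    data = []
    for acc in accessions:
        carried = {v.key for v in calls.get(acc, [])}
        data.append([1 if k in carried else 0 for k in keys])
    return VariantMatrix(
        variants=variants,
        genotypes=pd.DataFrame(data, index=accessions, columns=keys, dtype="int8"),
    )


@dataclass
class Haplotype:
    name: str
    profile: frozenset[str]  # alt-allele variant keys
    members: list[str]


@dataclass
class HaplotypeSet:
    """Named haplotype groups for one gene, plus not-determined accessions."""

    gene_id: str
    haplotypes: list[Haplotype] = field(default_factory=list)
    nd_accessions: list[str] = field(default_factory=list)
    elite_names: set[str] = field(default_factory=set)

    def name_of(self, accession: str) -> str:
        if accession in self.nd_accessions:
            return "n.d."
        for hap in self.haplotypes:
            if accession in hap.members:
                return hap.name
        raise KeyError(f"{accession} not in haplotype set for {self.gene_id}")

    def get(self, name: str) -> Haplotype:
        for hap in self.haplotypes:
            if hap.name == name:
                return hap
        raise KeyError(f"no haplotype {name!r} for {self.gene_id}")

    @property
    def named_profiles(self) -> dict[str, frozenset[str]]:
        return {h.name: h.profile for h in self.haplotypes}


def group_haplotypes(
    matrix: VariantMatrix,
    ref_accession: str,
    elite_profile: frozenset[str] | None = None,
    gene_id: str = "",
    nd_accessions: list[str] | None = None,
) -> HaplotypeSet:
    """Group accessions with identical genotype rows into named haplotypes.

    The reference accession's group is HapA; the group whose alt-allele set
    equals ``elite_profile`` is HapB (reserved empty, with a warning, when no
    accession carries it); the rest are HapC, HapD, ... by descending member
    count, ties broken by the alphabetically first member.
    """
    if ref_accession not in matrix.genotypes.index:
        raise ValueError(f"reference accession {ref_accession!r} not in matrix")
    nd = list(nd_accessions or [])
    groups: dict[frozenset[str], list[str]] = {}
    for acc in matrix.accessions:
        if acc in nd:
            continue
        groups.setdefault(matrix.alt_keys(acc), []).append(acc)

    ref_profile = matrix.alt_keys(ref_accession)
    haplotypes = [Haplotype("HapA", ref_profile, groups.pop(ref_profile))]
    next_letter = 1  # B
    if elite_profile is not None:
        elite_profile = frozenset(elite_profile)
        members = groups.pop(elite_profile, None)
        if members is None:
            warnings.warn(
                f"{gene_id or 'gene'}: elite profile matches no accession; "
                "HapB reserved but empty",
                stacklevel=2,
            )
            members = []
        haplotypes.append(Haplotype("HapB", elite_profile, members))
        next_letter = 2  # C
    remaining = sorted(groups.items(), key=lambda kv: (-len(kv[1]), min(kv[1])))
    for profile, members in remaining:
        haplotypes.append(Haplotype(f"Hap{chr(ord('A') + next_letter)}", profile, members))
        next_letter += 1
    elite_names = {"HapB"} if elite_profile is not None else set()
    return HaplotypeSet(
        gene_id=gene_id, haplotypes=haplotypes, nd_accessions=nd, elite_names=elite_names
    )


def flag_nd(
    accession: str,
    matrix: VariantMatrix | None,
    haps: HaplotypeSet,
    novel_threshold: int = 5,
) -> bool:
    """Not-determined rule: sequence unextractable, or many novel variants.

    An accession absent from the matrix (unextractable sequence) is n.d.;
    otherwise it is n.d. when it carries more than ``novel_threshold`` alt
    alleles found in no named haplotype profile.
    """
    if matrix is None or accession not in matrix.genotypes.index:
        return True
    known: set[str] = set()
    for profile in haps.named_profiles.values():
        known |= profile
    novel = matrix.alt_keys(accession) - known
    return len(novel) > novel_threshold


def classify_panel(
    loci: dict[str, LocusSequence],
    ref_accession: str,
    model: GeneModel | None = None,
    elite_profile: frozenset[str] | None = None,
    novel_threshold: int = 5,
    params: AlignParams = AlignParams(),
    expected_accessions: list[str] | None = None,
) -> tuple[VariantMatrix, HaplotypeSet]:
    """Align a locus panel to its reference, call variants and group haplotypes.

    Accessions listed in ``expected_accessions`` but missing from ``loci``
    (unextractable sequences) are reported as n.d.  Haplotype naming is done
    twice: a first pass defines the named profiles, against which accessions
    carrying more than ``novel_threshold`` novel variants are flagged n.d.
    and excluded from the final grouping.
    """
    ref = loci[ref_accession]
    calls = {
        acc: ([] if acc == ref_accession
              else call_variants(align_to_reference(locus, ref, params), ref, model))
        for acc, locus in loci.items()
    }
    matrix = build_matrix(calls, ref_accession)
    gene_id = ref.gene_id
    first = group_haplotypes(matrix, ref_accession, elite_profile, gene_id)
    shared = HaplotypeSet(
        gene_id=gene_id,
        haplotypes=[h for h in first.haplotypes if len(h.members) != 1
                    or ref_accession in h.members or h.name == "HapB"],
    )
    nd = [acc for acc in matrix.accessions
          if acc != ref_accession and flag_nd(acc, matrix, shared, novel_threshold)]
    for acc in expected_accessions or []:
        if acc not in matrix.genotypes.index and acc not in nd:
            nd.append(acc)
    haps = group_haplotypes(matrix, ref_accession, elite_profile, gene_id, nd_accessions=nd)
    return matrix, haps


# ---------------------------------------------------------------------------
# variant-table interchange


def write_variant_table(path, gene_id: str, matrix: VariantMatrix) -> None:
    """Write a long-format variant table (gene, accession, position, vtype,
    ref, alt, region), one row per carried alt allele."""
    with open(path, "w") as fh:
        fh.write("gene\taccession\tposition\tvtype\tref\talt\tregion\n")
        for acc in matrix.accessions:
            for key in sorted(matrix.alt_keys(acc)):
                v = matrix.variant_by_key(key)
                fh.write(
                    f"{gene_id}\t{acc}\t{v.position:+d}\t{v.vtype}\t"
                    f"{v.ref_allele}\t{v.alt_allele}\t{v.region}\n"
                )


def read_variant_table(path, gene_id: str, ref_accession: str,
                       accessions: list[str] | None = None) -> VariantMatrix:
    """Read a long-format variant table back into a matrix.

    This is the input path for variants too large to realign at desk scale
    (e.g. multi-kb structural insertions).
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    df = df[df["gene"] == gene_id]
    calls: dict[str, list[Variant]] = {acc: [] for acc in (accessions or [])}
    for _, row in df.iterrows():
        ref, alt = row["ref"], row["alt"]
        vtype = row["vtype"]
        delta = (0 if vtype == "SNP"
                 else (len(alt) if alt != GAP else 0) - (len(ref) if ref != GAP else 0))
        calls.setdefault(row["accession"], []).append(
            Variant(int(row["position"]), vtype, ref, alt,
                    str(row.get("region", "") or ""), delta)
        )
    return build_matrix(calls, ref_accession)
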