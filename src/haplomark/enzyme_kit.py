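"""IUPAC-aware restriction-site scanning and complete in-silico digestion.

The gel read-out of a CAPS/dCAPS assay is a list of fragment sizes, so only
top-strand cut positions are modelled; overhang geometry, methylation
sensitivity and partial digestion are out of scope.  Overlapping sites all
cut (complete-digestion model); duplicate cut positions collapse.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def revcomp(seq: str) -> str:
    """Reverse complement, IUPAC-aware."""
    return seq.translate(_COMPLEMENT)[::-1]


def iupac_regex(recognition: str) -> str:
    parts = []
    for base in recognition:
        allowed = IUPAC[base]
        parts.append(allowed if len(allowed) == 1 else f"[{allowed}]")
    return "".join(parts)


@dataclass(frozen=True)
class Enzyme:
    """A type II restriction enzyme.

    ``cut_offset`` is the distance in bases from the recognition site's 5'
    end to the top-strand cleavage point (0..len(recognition)); interrupted
    palindromes such as BglI (GCCNNNN^NGGC) cut inside the N tract.
    """

    name: str
    recognition: str
    cut_offset: int

    def __post_init__(self) -> None:
        rec = self.recognition.upper()
        if len(rec) < 4:
            raise ValueError(f"{self.name}: recognition shorter than 4 bp")
        bad = set(rec) - set(IUPAC)
        if bad:
            raise ValueError(f"{self.name}: non-IUPAC bases {sorted(bad)}")
        if not 0 <= self.cut_offset <= len(rec):
            raise ValueError(
                f"{self.name}: cut offset {self.cut_offset} outside recognition "
                f"of length {len(rec)}"
            )
        object.__setattr__(self, "recognition", rec)

    @property
    def is_palindromic(self) -> bool:
        return revcomp(self.recognition) == self.recognition

    def site_len(self) -> int:
        return len(self.recognition)


def find_sites(seq: str, enzyme: Enzyme) -> list[int]:
    """0-based start positions of recognition matches, either orientation.

    Overlapping matches are reported.  For non-palindromic recognitions the
    reverse-complement pattern is scanned as well; use :func:`find_sites_oriented`
    when the orientation of each hit matters.
    """
    return sorted({pos for pos, _ in find_sites_oriented(seq, enzyme)})


def find_sites_oriented(seq: str, enzyme: Enzyme) -> list[tuple[int, str]]:
    """Like :func:`find_sites` but each hit carries its strand, '+' or '-'."""
    seq = seq.upper()
    hits = [(m.start(), "+")
            for m in re.finditer(f"(?=({iupac_regex(enzyme.recognition)}))", seq)]
    if not enzyme.is_palindromic:
        rc = revcomp(enzyme.recognition)
        hits += [(m.start(), "-")
                 for m in re.finditer(f"(?=({iupac_regex(rc)}))", seq)]
    return sorted(hits)


def cut_positions(seq: str, enzyme: Enzyme) -> list[int]:
    """Top-strand cut points, deduplicated; 0 and len(seq) are excluded."""
    cuts = set()
    m = enzyme.site_len()
    for start, strand in find_sites_oriented(seq, enzyme):
        if strand == "+":
            cut = start + enzyme.cut_offset
        else:
            # reverse-orientation site: mirror the offset about the site
            cut = start + m - enzyme.cut_offset
        if 0 < cut < len(seq):
            cuts.add(cut)
    return sorted(cuts)


def digest(seq: str, enzyme: Enzyme) -> list[int]:
    """Fragment lengths of a complete digest, ordered 5'->3'.

    The fragments always sum to ``len(seq)``; a sequence with no site is
    returned as a single fragment.
    """
    if len(seq) < 1:
        raise ValueError("cannot digest an empty sequence")
    cuts = cut_positions(seq, enzyme)
    bounds = [0, *cuts, len(seq)]
    return [b - a for a, b in zip(bounds, bounds[1:])]


def differential_site(context_ref: str, context_alt: str, enzyme: Enzyme) -> str:
    """Classify which allele of a SNP carries a recognition site over the SNP.

    The two contexts are the same window around a SNP and must differ at
    exactly one base.  Returns ``ref_only``, ``alt_only``, ``both`` or
    ``neither``, where 'carries' means at least one site (either orientation)
    overlapping the differing position.
    """
    context_ref = context_ref.upper()
    context_alt = context_alt.upper()
    if context_ref == context_alt:
        raise ValueError("contexts are identical; not a SNP")
    if len(context_ref) != len(context_alt):
        raise ValueError("SNP contexts must have equal length")
    diffs = [i for i, (a, b) in enumerate(zip(context_ref, context_alt)) if a != b]
    if len(diffs) != 1:
        raise ValueError(f"contexts differ at {len(diffs)} positions, expected 1")
    snp = diffs[0]
    m = enzyme.site_len()

    def overlapping(seq: str) -> bool:
        return any(s <= snp < s + m for s in find_sites(seq, enzyme))

    ref_hit, alt_hit = overlapping(context_ref), overlapping(context_alt)
    if ref_hit and alt_hit:
        return "both"
    if ref_hit:
        return "ref_only"
    if alt_hit:
        return "alt_only"
    return "neither"
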