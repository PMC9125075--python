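"""Independent brute-force oracles used by the test suite.

These deliberately re-derive results by exhaustive enumeration, staying
independent of the library code paths they check.
"""

from __future__ import annotations

from functools import lru_cache

from haplomark.enzyme_kit import IUPAC, revcomp


def affine_optimum(
    a: str,
    b: str,
    match: float = 2.0,
    mismatch: float = -3.0,
    gap_open: float = -5.0,
    gap_extend: float = -2.0,
) -> float:
    """Optimal global alignment score over all alignments of ``a`` and ``b``
    with affine gaps (a gap of length k costs gap_open + k*gap_extend),
    computed by memoized exhaustive enumeration of alignment paths."""

    @lru_cache(maxsize=None)
    def best(i: int, j: int, last: str) -> float:
        if i == len(a) and j == len(b):
            return 0.0
        options = []
        if i < len(a) and j < len(b):
            sub = match if a[i] == b[j] else mismatch
            options.append(sub + best(i + 1, j + 1, "M"))
        if i < len(a):  # gap in b
            cost = gap_extend if last == "A" else gap_open + gap_extend
            options.append(cost + best(i + 1, j, "A"))
        if j < len(b):  # gap in a
            cost = gap_extend if last == "B" else gap_open + gap_extend
            options.append(cost + best(i, j + 1, "B"))
        return max(options)

    result = best(0, 0, "M")
    best.cache_clear()
    return result


def iupac_site_hits(seq: str, recognition: str) -> list[int]:
    """All recognition-match start positions (either orientation) by direct
    per-position comparison (no regex)."""
    hits = []
    patterns = {recognition}
    patterns.add(revcomp(recognition))
    m = len(recognition)
    for w in range(len(seq) - m + 1):
        for pat in patterns:
            if all(seq[w + i] in IUPAC[pat[i]] for i in range(m)):
                hits.append(w)
                break
    return hits


def dcaps_placements(
    seq: str,
    p: int,
    ref_base: str,
    alt_base: str,
    enzymes,
    primer_lens: range,
    max_sub: int = 1,
) -> set[tuple[str, int, int, str]]:
    """Brute-force enumeration of feasible dCAPS engineered-primer placements.

    Tries every primer window ending 5' of the SNP, every combination of at
    most ``max_sub`` substitutions at non-terminal positions within 1..5
    bases of the 3' end, and every substitute base; keeps placements where a
    recognition site spans primer and SNP for exactly one allele and
    overlaps at least one substituted position.  Returns
    (enzyme name, primer start, primer length, cut class) tuples.
    """
    out = set()
    for enz in enzymes:
        m = enz.site_len()
        for L in primer_lens:
            for end in range(L - 1, p):  # primer 3'-terminal offset
                start = end - L + 1
                if start < 0:
                    continue
                window = seq[start:end + 1]
                sub_positions = [j for j in range(L - 1) if 1 <= (L - 1 - j) <= 5]
                for j in sub_positions:
                    for b in "ACGT":
                        if b == window[j]:
                            continue
                        primer = window[:j] + b + window[j + 1:]
                        for allele, other in ((ref_base, alt_base), (alt_base, ref_base)):
                            t_yes = _overlay(seq, start, primer, p, allele)
                            t_no = _overlay(seq, start, primer, p, other)
                            hit_yes = _spanning_site(t_yes, enz, m, end, p, start + j)
                            hit_no = _spanning_site(t_no, enz, m, end, p, start + j)
                            if hit_yes and not hit_no:
                                cut = "ref" if allele == ref_base else "alt"
                                out.add((enz.name, start, L, cut))
    return out


def _overlay(seq: str, start: int, primer: str, p: int, allele: str) -> str:
    t = seq[:start] + primer + seq[start + len(primer):]
    return t[:p] + allele + t[p + 1:]


def _spanning_site(t: str, enz, m: int, primer_end: int, p: int, sub_pos: int) -> bool:
    return any(
        w <= primer_end and p < w + m and w <= sub_pos < w + m
        for w in iupac_site_hits(t, enz.recognition)
    )
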