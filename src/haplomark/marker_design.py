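"""Prioritized design of intragenic genotyping assays for elite haplotypes.

Candidate variants are the ones private to the target haplotype(s).  The
design cascade then tries, in order:

1. an Indel marker for a 5-30 bp indel (100-300 bp amplicon, sized on PAGE);
2. a CAPS marker for a SNP that naturally creates/destroys a common
   restriction site (100-500 bp amplicon, agarose);
3. a dCAPS marker, engineering <=1 primer mismatch near the 3' end so that
   one allele completes a restriction site (100-300 bp amplicon, PAGE);
4. a PARMS marker: two universally tailed allele-specific forward primers
   (FAM/HEX read-out) plus one common reverse primer.

Indels far outside the size window (whole-segment replacements) can still be
emitted as structural markers with relaxed amplicon bounds and a warning
note, since a single large event is sometimes the only diagnostic variant a
gene offers.

Marker names follow the "gene label + region code + variant-type code"
scheme: region 5U/E<k>/I<k>/3U, type ID for indels and S for SNP assays,
e.g. "NPF6.1 5U ID" or "SBM1 E3 S".
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path

from Bio.SeqUtils import MeltingTemp as mt

from .enzyme_kit import IUPAC, Enzyme, digest, differential_site, find_sites, revcomp
from .locus_io import EnzymeCatalog, FormatError, LocusSequence, default_enzyme_catalog
from .variant_haplotype import (
    HaplotypeSet,
    Variant,
    VariantMatrix,
    position_to_offset,
)

FAM_TAIL = "GAAGGTGACCAAGTTCATGCT"
HEX_TAIL = "GAAGGTCGGAGTCAACGGATT"


class DesignError(RuntimeError):
    """A design stage (or the whole cascade) found no feasible assay."""

    def __init__(self, message: str, failures: dict[str, str] | None = None):
        super().__init__(message)
        self.failures = failures or {}


@dataclass(frozen=True)
class DesignConfig:
    """Tunable design rules; the defaults are the published rule set."""

    indel_min: int = 5
    indel_max: int = 30
    indel_amplicon: tuple[int, int] = (100, 300)
    caps_amplicon: tuple[int, int] = (100, 500)
    dcaps_amplicon: tuple[int, int] = (100, 300)
    primer_len: tuple[int, int] = (18, 24)
    tm_range: tuple[float, float] = (52.0, 62.0)
    gc_range: tuple[float, float] = (35.0, 65.0)
    max_dcaps_mismatches: int = 1
    tail_fam: str = FAM_TAIL
    tail_hex: str = HEX_TAIL
    gel_resolution_page: int = 4
    gel_resolution_agarose: int = 20
    min_cut_fragment: int = 20
    max_mono_run: int = 4
    allow_structural_override: bool = True
    structural_amplicon_max: int = 1500
    pcr_max_product: int = 5000
    pcr_max_mismatch: int = 1


@dataclass
class MarkerAssay:
    """A designed (or transcribed) genotyping assay.

    ``primers`` maps role (F/R, or FC/FT/R for PARMS) to sequence; engineered
    dCAPS bases are lowercase in place, PARMS tails are part of FC/FT.
    ``expected`` maps allele class ('ref'/'alt') to its read-out: a fragment
    length list for gel assays or a fluorophore name for PARMS.
    """

    name: str
    gene_id: str
    gene_label: str
    mtype: str  # Indel | CAPS | dCAPS | PARMS
    variation_position: int
    target_haplotypes: tuple[str, ...]
    primers: dict[str, str]
    expected: dict[str, object]
    enzyme: Enzyme | None = None
    target_variant: Variant | None = None
    rule_fired: str = ""
    notes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.mtype not in ("Indel", "CAPS", "dCAPS", "PARMS"):
            raise ValueError(f"unknown marker type {self.mtype!r}")
        if self.mtype == "Indel" and self.enzyme is not None:
            raise ValueError(f"{self.name}: Indel markers carry no enzyme")
        if self.mtype in ("CAPS", "dCAPS"):
            if self.enzyme is None:
                raise ValueError(f"{self.name}: {self.mtype} needs an enzyme")
            if sorted(self.expected["ref"]) == sorted(self.expected["alt"]):
                raise ValueError(f"{self.name}: allele classes do not differ")
        if self.mtype == "PARMS":
            fc, ft = self.primers["FC"], self.primers["FT"]
            core_c = _strip_tail(fc)
            core_t = _strip_tail(ft)
            if core_c[:-1] != core_t[:-1] or core_c[-1] == core_t[-1]:
                raise ValueError(
                    f"{self.name}: FC/FT must differ only in tail and 3'-terminal base"
                )

    def engineered_positions(self, role: str) -> list[tuple[int, str]]:
        """(index, base) of lowercase (engineered) positions in a primer."""
        return [(i, b.upper()) for i, b in enumerate(self.primers[role]) if b.islower()]

    def binding_seq(self, role: str) -> str:
        """The template-binding part of a primer, uppercased, tails stripped."""
        seq = self.primers[role].upper()
        if self.mtype == "PARMS" and role in ("FC", "FT"):
            return _strip_tail(self.primers[role]).upper()
        return seq


def _strip_tail(primer: str) -> str:
    for tail in (FAM_TAIL, HEX_TAIL):
        if primer.upper().startswith(tail):
            return primer[len(tail):]
    raise ValueError("PARMS primer does not start with a known universal tail")


# ---------------------------------------------------------------------------
# primer arithmetic


def gc_percent(seq: str) -> float:
    seq = seq.upper()
    return 100.0 * sum(seq.count(b) for b in "GC") / len(seq)


@lru_cache(maxsize=1 << 16)
def melting_temp(seq: str) -> float:
    """Primer Tm: nearest-neighbor (50 mM Na+, 250 nM primer); the Wallace
    2(A+T)+4(G+C) rule for primers shorter than 14 nt."""
    seq = seq.upper()
    if len(seq) < 14:
        return mt.Tm_Wallace(seq)
    return mt.Tm_NN(seq, Na=50, dnac1=250, dnac2=0)


def max_mono_run(seq: str) -> int:
    return max(len(m.group(0)) for m in re.finditer(r"(.)\1*", seq.upper()))


def _primer_ok(seq: str, cfg: DesignConfig) -> bool:
    if not cfg.primer_len[0] <= len(seq) <= cfg.primer_len[1]:
        return False
    if not cfg.gc_range[0] <= gc_percent(seq) <= cfg.gc_range[1]:
        return False
    if max_mono_run(seq) > cfg.max_mono_run:
        return False
    return cfg.tm_range[0] <= melting_temp(seq) <= cfg.tm_range[1]


def _pair_3prime_clash(fwd: str, rev: str, k: int = 4) -> bool:
    """True when the 3' end of either primer can anneal >=k bp to the other."""
    f, r = fwd.upper(), rev.upper()
    return revcomp(f[-k:]) in r or revcomp(r[-k:]) in f


@dataclass(frozen=True)
class PrimerPair:
    fwd: str
    rev: str
    fwd_start: int  # 0-based template offset of the forward primer 5' end
    amplicon_len: int

    @property
    def amplicon_end(self) -> int:  # exclusive
        return self.fwd_start + self.amplicon_len


def design_primer_pair(
    template: str,
    must_span: tuple[int, int],
    amplicon_range: tuple[int, int],
    cfg: DesignConfig = DesignConfig(),
    fixed_forward: tuple[int, str] | None = None,
) -> PrimerPair:
    """Pick a deterministic primer pair whose amplicon spans ``must_span``.

    ``must_span`` is (lo, hi): the forward primer must end before ``lo`` and
    the reverse primer's binding region must start after ``hi`` (an empty
    interval ``(i, i-1)`` encodes a point between two bases).  Choice is
    deterministic: smallest amplicon, then highest minimum Tm, then leftmost
    forward primer.  Raises :class:`DesignError` naming the binding
    constraint when infeasible.
    """
    template = template.upper()
    n = len(template)
    lo, hi = must_span
    min_amp, max_amp = amplicon_range
    if n < min_amp:
        raise DesignError(f"template of {n} bp shorter than minimum amplicon {min_amp}")
    min_len, max_len = cfg.primer_len

    if fixed_forward is not None:
        fstart, fseq = fixed_forward
        fwd_by_start = {fstart: [(fseq, melting_temp(fseq.upper()))]}
    else:
        fwd_by_start: dict[int, list[tuple[str, float]]] = {}
        for start in range(max(0, lo - max_amp), lo - min_len + 1):
            for length in range(min_len, max_len + 1):
                end = start + length  # exclusive
                if end > lo:
                    break
                seq = template[start:end]
                if _primer_ok(seq, cfg):
                    fwd_by_start.setdefault(start, []).append((seq, melting_temp(seq)))
        if not fwd_by_start:
            raise DesignError("no valid forward primer (length/Tm/GC/run constraints)")

    rev_by_end: dict[int, list[tuple[str, float]]] = {}
    rev_lo = hi + 1 + min_len - 1
    rev_hi = min(n - 1, hi + max_amp)
    for end in range(rev_lo, rev_hi + 1):  # inclusive amplicon end index
        for length in range(min_len, max_len + 1):
            start = end - length + 1
            if start <= hi:
                break
            seq = revcomp(template[start:end + 1])
            if _primer_ok(seq, cfg):
                rev_by_end.setdefault(end, []).append((seq, melting_temp(seq)))
    if not rev_by_end:
        raise DesignError("no valid reverse primer (length/Tm/GC/run constraints)")

    for amp in range(min_amp, max_amp + 1):
        best: tuple[float, int, PrimerPair] | None = None
        for fstart, fwd_opts in fwd_by_start.items():
            rend = fstart + amp - 1
            if rend not in rev_by_end:
                continue
            for fseq, ftm in fwd_opts:
                for rseq, rtm in rev_by_end[rend]:
                    if _pair_3prime_clash(fseq, rseq):
                        continue
                    cand = (min(ftm, rtm), -fstart, PrimerPair(fseq, rseq, fstart, amp))
                    if best is None or cand[:2] > best[:2]:
                        best = cand
        if best is not None:
            return best[2]
    raise DesignError(
        f"no primer pair yields an amplicon in [{min_amp}, {max_amp}] spanning the target"
    )


# ---------------------------------------------------------------------------
# target selection and naming


def select_target_variants(
    haps: HaplotypeSet, matrix: VariantMatrix, targets: set[str] | tuple[str, ...]
) -> list[Variant]:
    """Variants whose alt allele is carried by every target-haplotype member
    and by no member of any other named haplotype (n.d. accessions ignored)."""
    targets = set(targets)
    unknown = targets - set(haps.named_profiles)
    if unknown:
        raise KeyError(f"unknown target haplotypes {sorted(unknown)}")
    target_members = [m for h in haps.haplotypes if h.name in targets for m in h.members]
    other_members = [m for h in haps.haplotypes if h.name not in targets for m in h.members]
    out = []
    for v in matrix.variants:
        if v.has_ambiguous_allele:
            continue
        col = matrix.genotypes[v.key]
        if target_members and all(col[m] == 1 for m in target_members) and not any(
            col[m] == 1 for m in other_members
        ):
            out.append(v)
    return out


def name_marker(gene_label: str, region: str, mtype: str) -> str:
    """"gene label + region + type code": ID for Indel, S for SNP-based."""
    code = "ID" if mtype == "Indel" else "S"
    return f"{gene_label} {region} {code}"


# ---------------------------------------------------------------------------
# stage designers


def design_indel(
    variant: Variant,
    ref_locus: LocusSequence,
    cfg: DesignConfig = DesignConfig(),
    gene_label: str | None = None,
    targets: tuple[str, ...] = ("HapB",),
    structural: bool = False,
) -> MarkerAssay:
    """Indel marker: primers flank the indel, alleles differ in amplicon size."""
    if variant.vtype not in ("INS", "DEL", "SUB"):
        raise DesignError(f"{variant.key}: not an indel")
    delta = variant.size_delta
    in_window = cfg.indel_min <= abs(delta) <= cfg.indel_max
    if not in_window and not structural:
        raise DesignError(
            f"indel size {abs(delta)} outside [{cfg.indel_min}, {cfg.indel_max}] bp"
        )
    if abs(delta) < cfg.gel_resolution_page:
        raise DesignError(
            f"size difference {abs(delta)} bp unresolvable on PAGE "
            f"({cfg.gel_resolution_page} bp)"
        )
    start = position_to_offset(variant.position, ref_locus)
    if variant.vtype == "INS":
        must_span = (start, start - 1)
    else:
        must_span = (start, start + len(variant.ref_allele) - 1)
    if structural:
        margin = 2 * cfg.primer_len[1] + 50
        needed = (must_span[1] - must_span[0] + 1) + margin
        amp_range = (cfg.indel_amplicon[0], max(cfg.structural_amplicon_max, needed))
    else:
        amp_range = cfg.indel_amplicon
    pair = design_primer_pair(ref_locus.seq, must_span, amp_range, cfg)
    label = gene_label or ref_locus.gene_id
    notes = []
    if structural:
        notes.append(
            f"structural override: {abs(delta)}-bp size change outside the "
            f"{cfg.indel_min}-{cfg.indel_max} bp rule; relaxed amplicon bounds"
        )
    return MarkerAssay(
        name=name_marker(label, variant.region or "5U", "Indel"),
        gene_id=ref_locus.gene_id,
        gene_label=label,
        mtype="Indel",
        variation_position=variant.position,
        target_haplotypes=tuple(targets),
        primers={"F": pair.fwd, "R": pair.rev},
        expected={"ref": [pair.amplicon_len], "alt": [pair.amplicon_len + delta]},
        target_variant=variant,
        rule_fired="structural" if structural else "indel",
        notes=notes,
    )


def _snp_contexts(snp: Variant, ref_locus: LocusSequence, half: int) -> tuple[str, str, int]:
    p = position_to_offset(snp.position, ref_locus)
    lo, hi = max(0, p - half), min(len(ref_locus.seq), p + half + 1)
    ctx_ref = ref_locus.seq[lo:hi]
    center = p - lo
    if ctx_ref[center] != snp.ref_allele:
        raise DesignError(
            f"{snp.key}: reference locus has {ctx_ref[center]} at {snp.position:+d}"
        )
    ctx_alt = ctx_ref[:center] + snp.alt_allele + ctx_ref[center + 1:]
    return ctx_ref, ctx_alt, p


def design_caps(
    snp: Variant,
    ref_locus: LocusSequence,
    cfg: DesignConfig = DesignConfig(),
    enzymes: EnzymeCatalog | None = None,
    gene_label: str | None = None,
    targets: tuple[str, ...] = ("HapB",),
) -> MarkerAssay:
    """CAPS marker: the SNP naturally gains/loses a catalog enzyme site."""
    if snp.vtype != "SNP":
        raise DesignError(f"{snp.key}: CAPS needs a SNP")
    if enzymes is None:
        enzymes = default_enzyme_catalog()
    failures = []
    for enzyme in enzymes:
        m = enzyme.site_len()
        ctx_ref, ctx_alt, p = _snp_contexts(snp, ref_locus, m - 1)
        direction = differential_site(ctx_ref, ctx_alt, enzyme)
        if direction not in ("ref_only", "alt_only"):
            continue
        cut_ctx = ctx_ref if direction == "ref_only" else ctx_alt
        center = min(p, m - 1)
        site = next(s for s in find_sites(cut_ctx, enzyme) if s <= center < s + m)
        site_start = p - center + site
        # pad so both cut fragments clear the gel-visible minimum
        span = (site_start - cfg.min_cut_fragment, site_start + m - 1 + cfg.min_cut_fragment)
        try:
            pair = design_primer_pair(ref_locus.seq, span, cfg.caps_amplicon, cfg)
        except DesignError as exc:
            failures.append(f"{enzyme.name}: {exc}")
            continue
        amp_ref = ref_locus.seq[pair.fwd_start:pair.amplicon_end]
        off = p - pair.fwd_start
        amp_alt = amp_ref[:off] + snp.alt_allele + amp_ref[off + 1:]
        frag_ref, frag_alt = digest(amp_ref, enzyme), digest(amp_alt, enzyme)
        cut_frags = frag_ref if direction == "ref_only" else frag_alt
        if len(cut_frags) < 2 or min(cut_frags) < cfg.min_cut_fragment:
            failures.append(f"{enzyme.name}: diagnostic fragment below gel-visible minimum")
            continue
        if not patterns_distinguishable(frag_ref, frag_alt, cfg.gel_resolution_agarose):
            failures.append(f"{enzyme.name}: allele patterns unresolvable on agarose")
            continue
        label = gene_label or ref_locus.gene_id
        return MarkerAssay(
            name=name_marker(label, snp.region or "5U", "CAPS"),
            gene_id=ref_locus.gene_id,
            gene_label=label,
            mtype="CAPS",
            variation_position=snp.position,
            target_haplotypes=tuple(targets),
            primers={"F": pair.fwd, "R": pair.rev},
            expected={"ref": frag_ref, "alt": frag_alt},
            enzyme=enzyme,
            target_variant=snp,
            rule_fired="caps",
        )
    detail = "; ".join(failures) if failures else "no enzyme gains/loses a site at the SNP"
    raise DesignError(f"CAPS infeasible: {detail}")


def _iupac_match(base: str, code: str) -> bool:
    return base in IUPAC[code]


def dcaps_candidates(
    snp: Variant,
    ref_locus: LocusSequence,
    cfg: DesignConfig,
    enzymes: EnzymeCatalog,
) -> list[dict]:
    """Enumerate feasible engineered-primer placements for a dCAPS assay.

    For each enzyme and each placement of its recognition window over the
    SNP, a forward primer ending 1..(site length - 1) bases 5' of the SNP is
    engineered so primer + template completes the site for exactly one
    allele.  Engineered substitutions sit at primer positions -2..-6 from
    the 3' end (never the terminal base), at most ``max_dcaps_mismatches``
    of them.  Candidates come back in deterministic search order.
    """
    if snp.vtype != "SNP":
        raise DesignError(f"{snp.key}: dCAPS needs a SNP")
    seq = ref_locus.seq
    p = position_to_offset(snp.position, ref_locus)
    out = []
    for enzyme in enzymes:
        patterns = [enzyme.recognition]
        if not enzyme.is_palindromic:
            patterns.append(revcomp(enzyme.recognition))
        m = enzyme.site_len()
        for pattern in patterns:
            for w in range(p - m + 1, p + 1):  # site covers the SNP
                if w < 0 or w + m > len(seq):
                    continue
                # template part (beyond the primer) must match for ref bases,
                # with the SNP position deciding the allele
                ref_ok = _iupac_match(snp.ref_allele, pattern[p - w])
                alt_ok = _iupac_match(snp.alt_allele, pattern[p - w])
                if ref_ok == alt_ok:
                    continue  # site indifferent to the allele
                for q in range(w, p):  # primer 3'-terminal template offset
                    if not _iupac_match(seq[q], pattern[q - w]):
                        continue  # would need an engineered terminal base
                    if any(
                        i != p and not _iupac_match(seq[i], pattern[i - w])
                        for i in range(q + 1, w + m)
                    ):
                        continue  # template part can't complete the site
                    for length in range(cfg.primer_len[0], cfg.primer_len[1] + 1):
                        start = q - length + 1
                        if start < 0:
                            continue
                        primer = list(seq[start:q + 1])
                        engineered = []
                        feasible = True
                        for i in range(w, q):  # site bases under the primer
                            idx = i - start
                            code = pattern[i - w]
                            if _iupac_match(seq[i], code):
                                continue
                            sub = next(b for b in "ACGT" if _iupac_match(b, code))
                            # 3'-terminal base is position -1 (distance 0);
                            # the allowed -2..-6 window is distance 1..5
                            dist_from_3p = length - 1 - idx
                            if not 1 <= dist_from_3p <= 5:
                                feasible = False
                                break
                            primer[idx] = sub.lower()
                            engineered.append((idx, sub))
                        if not feasible or not engineered:
                            continue  # no mismatch needed means CAPS territory
                        if len(engineered) > cfg.max_dcaps_mismatches:
                            continue
                        pseq = "".join(primer)
                        if not _primer_ok(pseq.upper(), cfg):
                            continue
                        out.append({
                            "enzyme": enzyme,
                            "pattern": pattern,
                            "site_start": w,
                            "primer_start": start,
                            "primer": pseq,
                            "engineered": engineered,
                            "cut_class": "ref" if ref_ok else "alt",
                        })
    return out


def design_dcaps(
    snp: Variant,
    ref_locus: LocusSequence,
    cfg: DesignConfig = DesignConfig(),
    enzymes: EnzymeCatalog | None = None,
    gene_label: str | None = None,
    targets: tuple[str, ...] = ("HapB",),
) -> MarkerAssay:
    """dCAPS marker: an engineered primer mismatch creates an allele-specific
    site; digestion clips a short primer-side fragment off the cut class."""
    if enzymes is None:
        enzymes = default_enzyme_catalog()
    p = position_to_offset(snp.position, ref_locus)
    for cand in dcaps_candidates(snp, ref_locus, cfg, enzymes):
        try:
            pair = design_primer_pair(
                ref_locus.seq,
                (p, p),
                cfg.dcaps_amplicon,
                cfg,
                fixed_forward=(cand["primer_start"], cand["primer"]),
            )
        except DesignError:
            continue
        amp_template = ref_locus.seq[cand["primer_start"]:pair.amplicon_end]
        amp_ref = cand["primer"].upper() + amp_template[len(cand["primer"]):]
        off = p - cand["primer_start"]
        amp_alt = amp_ref[:off] + snp.alt_allele + amp_ref[off + 1:]
        frag_ref = digest(amp_ref, cand["enzyme"])
        frag_alt = digest(amp_alt, cand["enzyme"])
        if sorted(frag_ref) == sorted(frag_alt):
            continue
        if not patterns_distinguishable(frag_ref, frag_alt, cfg.gel_resolution_page):
            continue
        label = gene_label or ref_locus.gene_id
        return MarkerAssay(
            name=name_marker(label, snp.region or "5U", "dCAPS"),
            gene_id=ref_locus.gene_id,
            gene_label=label,
            mtype="dCAPS",
            variation_position=snp.position,
            target_haplotypes=tuple(targets),
            primers={"F": cand["primer"], "R": pair.rev},
            expected={"ref": frag_ref, "alt": frag_alt},
            enzyme=cand["enzyme"],
            target_variant=snp,
            rule_fired="dcaps",
        )
    raise DesignError("dCAPS infeasible: exhaustive enzyme x placement search empty")


def design_parms(
    snp: Variant,
    ref_locus: LocusSequence,
    cfg: DesignConfig = DesignConfig(),
    gene_label: str | None = None,
    targets: tuple[str, ...] = ("HapB",),
) -> MarkerAssay:
    """PARMS marker: FAM/HEX-tailed allele-specific forward primers sharing a
    common core, plus one common reverse primer."""
    if snp.vtype != "SNP":
        raise DesignError(f"{snp.key}: PARMS needs a SNP")
    if not cfg.tail_fam or not cfg.tail_hex:
        raise DesignError("PARMS design needs both universal tails configured")
    p = position_to_offset(snp.position, ref_locus)
    core = None
    for length in range(cfg.primer_len[0], cfg.primer_len[1] + 1):
        start = p - length + 1
        if start < 0:
            continue
        cand = ref_locus.seq[start:p + 1]  # 3'-terminal base is the SNP
        if _primer_ok(cand, cfg):
            core = (start, cand)
            break
    if core is None:
        raise DesignError("no allele-specific core meets length/Tm/GC constraints")
    start, core_seq = core
    pair = design_primer_pair(
        ref_locus.seq, (p, p), cfg.dcaps_amplicon, cfg, fixed_forward=(start, core_seq)
    )
    fc = cfg.tail_fam + core_seq[:-1] + snp.ref_allele
    ft = cfg.tail_hex + core_seq[:-1] + snp.alt_allele
    label = gene_label or ref_locus.gene_id
    return MarkerAssay(
        name=name_marker(label, snp.region or "5U", "PARMS"),
        gene_id=ref_locus.gene_id,
        gene_label=label,
        mtype="PARMS",
        variation_position=snp.position,
        target_haplotypes=tuple(targets),
        primers={"FC": fc, "FT": ft, "R": pair.rev},
        expected={"ref": "FAM", "alt": "HEX"},
        target_variant=snp,
        rule_fired="parms",
    )


def design_cascade(
    candidates: list[Variant],
    ref_locus: LocusSequence,
    alt_locus: LocusSequence | None = None,
    cfg: DesignConfig = DesignConfig(),
    enzymes: EnzymeCatalog | None = None,
    gene_label: str | None = None,
    targets: tuple[str, ...] = ("HapB",),
) -> MarkerAssay:
    """Run the Indel -> CAPS -> dCAPS -> PARMS priority cascade.

    Returns the first stage's success; raises :class:`DesignError` carrying
    per-stage failure reasons when nothing is feasible.  ``alt_locus`` is
    accepted for symmetry with the wet-lab workflow but design operates on
    the reference locus (alt alleles come from the variants).
    """
    if not candidates:
        raise DesignError("no candidate variants unique to the target haplotypes")
    if enzymes is None:
        enzymes = default_enzyme_catalog()
    failures: dict[str, str] = {}
    indels = [v for v in candidates if v.vtype in ("INS", "DEL", "SUB")]
    snps = [v for v in candidates if v.vtype == "SNP"]

    sized = [v for v in indels if cfg.indel_min <= abs(v.size_delta) <= cfg.indel_max]
    stage_errors = []
    for v in sized:
        try:
            return design_indel(v, ref_locus, cfg, gene_label, targets)
        except DesignError as exc:
            stage_errors.append(f"{v.key}: {exc}")
    failures["indel"] = "; ".join(stage_errors) or "no indel candidate in the 5-30 bp window"

    for stage, designer in (("caps", design_caps), ("dcaps", design_dcaps)):
        stage_errors = []
        for v in snps:
            try:
                if stage == "caps":
                    return design_caps(v, ref_locus, cfg, enzymes, gene_label, targets)
                return design_dcaps(v, ref_locus, cfg, enzymes, gene_label, targets)
            except DesignError as exc:
                stage_errors.append(f"{v.key}: {exc}")
        failures[stage] = "; ".join(stage_errors) or "no SNP candidate"

    stage_errors = []
    for v in snps:
        try:
            return design_parms(v, ref_locus, cfg, gene_label, targets)
        except DesignError as exc:
            stage_errors.append(f"{v.key}: {exc}")
    failures["parms"] = "; ".join(stage_errors) or "no SNP candidate"

    if cfg.allow_structural_override:
        stage_errors = []
        for v in indels:
            if v in sized:
                continue
            try:
                return design_indel(v, ref_locus, cfg, gene_label, targets, structural=True)
            except DesignError as exc:
                stage_errors.append(f"{v.key}: {exc}")
        failures["structural"] = "; ".join(stage_errors) or "no out-of-window indel"

    raise DesignError("no design possible for any candidate variant", failures)


def patterns_distinguishable(a: list[int], b: list[int], resolution: int) -> bool:
    """Gel model: two band patterns differ when no pairing of their bands
    keeps every size difference below the resolution threshold."""
    a, b = sorted(a), sorted(b)
    if len(a) != len(b):
        return True
    return any(abs(x - y) >= resolution for x, y in zip(a, b))


# ---------------------------------------------------------------------------
# marker-table interchange (size encodings per the published footnote)


def parse_size_encoding(text: str, mtype: str) -> dict[str, object]:
    """Parse a reference-size encoding into per-class expected read-outs.

    Indel: ``"220 (+20)"`` = 220-bp reference amplicon, elite allele +20 bp.
    CAPS/dCAPS: ``"X/(a,b)"`` or ``"(a,b)/X"`` with the reference pattern
    before the slash and the elite pattern after it.  PARMS markers have no
    size encoding (``"-"``).
    """
    text = text.strip()
    if mtype == "PARMS":
        if text not in ("", "-"):
            raise FormatError(f"PARMS markers carry no size encoding, got {text!r}")
        return {"ref": "FAM", "alt": "HEX"}
    if mtype == "Indel":
        m = re.fullmatch(r"(\d+)\s*\(([+-]\d+)\)", text)
        if not m:
            raise FormatError(f"bad Indel size encoding {text!r}")
        ref_size, delta = int(m.group(1)), int(m.group(2))
        return {"ref": [ref_size], "alt": [ref_size + delta]}
    parts = text.split("/")
    if len(parts) != 2:
        raise FormatError(f"bad {mtype} size encoding {text!r}")

    def side(s: str) -> list[int]:
        s = s.strip()
        if s.startswith("(") and s.endswith(")"):
            return [int(x) for x in s[1:-1].split(",")]
        return [int(s)]

    return {"ref": side(parts[0]), "alt": side(parts[1])}


def format_size_encoding(marker: MarkerAssay) -> str:
    if marker.mtype == "PARMS":
        return "-"
    ref, alt = marker.expected["ref"], marker.expected["alt"]
    if marker.mtype == "Indel":
        delta = alt[0] - ref[0]
        return f"{ref[0]} ({delta:+d})"

    def side(frags: list[int]) -> str:
        return str(frags[0]) if len(frags) == 1 else "(" + ",".join(map(str, frags)) + ")"

    return f"{side(ref)}/{side(alt)}"


_TABLE_COLUMNS = [
    "gene", "gene_label", "variation_position", "marker_type", "marker_name",
    "primer_role", "primer_sequence", "reference_size", "enzyme", "target_haplotypes",
]


def read_marker_table(path: str | Path, enzymes: EnzymeCatalog | None = None) -> list[MarkerAssay]:
    """Read a marker table (one row per primer) into assays.

    Size encodings round-trip bit-exact through :func:`write_marker_table`.
    """
    if enzymes is None:
        enzymes = default_enzyme_catalog()
    rows = []
    with open(path) as fh:
        header = None
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if header is None:
                header = parts
                if header != _TABLE_COLUMNS:
                    raise FormatError(f"marker table header must be {_TABLE_COLUMNS}")
                continue
            rows.append(dict(zip(header, parts)))
    markers: list[MarkerAssay] = []
    by_name: dict[str, list[dict]] = {}
    for row in rows:
        by_name.setdefault(row["marker_name"], []).append(row)
    for name, group in by_name.items():
        first = group[0]
        mtype = first["marker_type"]
        primers = {r["primer_role"]: r["primer_sequence"] for r in group}
        enzyme = None if first["enzyme"] in ("-", "") else enzymes.get(first["enzyme"])
        markers.append(MarkerAssay(
            name=name,
            gene_id=first["gene"],
            gene_label=first["gene_label"],
            mtype=mtype,
            variation_position=int(first["variation_position"]),
            target_haplotypes=tuple(first["target_haplotypes"].split(",")),
            primers=primers,
            expected=parse_size_encoding(first["reference_size"], mtype),
            enzyme=enzyme,
        ))
    return markers


def write_marker_table(path: str | Path, markers: list[MarkerAssay],
                       header_comment: str | None = None) -> None:
    with open(path, "w") as fh:
        if header_comment:
            for line in header_comment.rstrip("\n").split("\n"):
                fh.write(f"# {line}\n")
        fh.write("\t".join(_TABLE_COLUMNS) + "\n")
        for m in markers:
            enc = format_size_encoding(m)
            for role, seq in m.primers.items():
                enz = m.enzyme.name if m.enzyme else "-"
                size = enc if role in ("F", "R") and m.mtype != "PARMS" else (
                    enc if m.mtype != "PARMS" else "-")
                fh.write("\t".join([
                    m.gene_id, m.gene_label, f"{m.variation_position:+d}", m.mtype,
                    m.name, role, seq, size, enz, ",".join(m.target_haplotypes),
                ]) + "\n")
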