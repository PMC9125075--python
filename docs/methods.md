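# Methods

This note documents the models, conventions and numerical choices behind
`haplomark`, and what its synthetic fixtures do and do not establish.

## The analysed gene region

A gene's analysed locus is the 2-kb flank upstream of the A of the start
codon, the gene body through the last stop-codon base, and the 1-kb flank
downstream. The flank labels "5U" and "3U" follow loose field usage for this
workflow — they are fixed windows, not transcript UTRs — and are kept for
traceability with the marker-naming scheme. Equal windows across accessions
are what make haplotype profiles comparable, so a flank running off a contig
is an error by default; `allow_truncation` downgrades it to a warning and
records the actual flank length. Input genomic coordinates are 1-based
inclusive (GFF convention); all internal offsets are 0-based. Minus-strand
genes are reverse-complemented at extraction so every downstream step sees a
plus-oriented locus.

Positions are reported in the signed ATG-relative convention used throughout
rice gene-haplotype work: +1 is the A of ATG, −1 the base immediately 5′ of
it, there is no position 0, and positive coordinates run through introns
(e.g. a position ~3.3 kb into the gene can sit in the sixth intron). Region
labels are 5U, E\<k\>, I\<k\> (exon/intron ordinals in transcription order)
and 3U.

## Alignment and variant calling

Accession loci are aligned to the reference accession with a global
affine-gap aligner (Biopython's `PairwiseAligner` behind the module
surface). Defaults: match +2, mismatch −3, gap open −5, gap extend −2 per
gap base (a length-k gap costs −5 − 2k). The heavy gap-open penalty makes a
single long indel cheaper than fragmented gaps, which matches how gene-region
indels present (single 20–600 bp events). Ties are broken deterministically
by taking the aligner's first traceback. Global alignment is practical to
roughly 20-kb loci on one core; variants from larger structural events
(multi-kb insertions) should enter through the variant-table input instead
of realignment.

Variant normalization: adjacent gap columns merge into one insertion or
deletion; an adjacent deletion+insertion pair merges into a replacement
(SUB); equal-length mismatch runs decompose into per-base SNPs; indels are
left-aligned in repeat tracts and positioned at the first affected reference
base (insertions at the reference base immediately 3′ of the insertion
point). This mirrors VCF community practice and makes planted-variant
recovery exact.

Panel accessions are modelled as inbred (homozygous) lines — germplasm
accessions and cultivars — so genotypes are binary ref/alt per variant and
heterozygous input is rejected.

## Haplotype grouping and the n.d. rule

Accessions with identical genotype rows share a haplotype. The reference
accession's profile is HapA; the profile designated elite is HapB (reserved,
with a warning, if no accession carries it); remaining groups are HapC,
HapD, … by descending member count, ties broken by the alphabetically first
member. The frequency-then-lexicographic order for non-elite haplotypes is a
repo convention: published tables do not state how co-frequent sub-haplotypes
were ordered.

An accession is "n.d." for a gene when its sequence cannot be extracted or
when it carries more than `novel_threshold` alt alleles found in no named
haplotype profile. The threshold defaults to 5; the source workflow says
only "many novel variations", so 5 is a package choice — small enough to
quarantine divergent alleles, large enough to tolerate a private SNP or two.

## Marker design

Candidate variants are those carried by every member of the target
haplotype(s) and by no member of any other named haplotype (n.d. accessions
ignored). The cascade then applies the published priority rules:

1. **Indel**, 5 ≤ |Δ| ≤ 30 bp, amplicon 100–300 bp, read on 4%
   polyacrylamide (modelled resolution 4 bp).
2. **CAPS**: a SNP creating/destroying a site of a catalog enzyme, amplicon
   100–500 bp, read on 2% agarose (modelled resolution 20 bp); both
   diagnostic fragments must be ≥20 bp.
3. **dCAPS**: amplicon 100–300 bp; the forward primer carries at most one
   engineered substitution at positions −2…−6 from the 3′ end (never the
   terminal base, which must match the template so the primer still
   extends), chosen so primer + template completes a recognition site for
   exactly one allele. The −2…−6 window is standard dCAPS practice. The
   search enumerates enzymes × site placements × primer ends and is verified
   against brute-force enumeration on toy contexts. Only top-strand forward
   primers are engineered; reverse-primer engineering is a known omission.
4. **PARMS** (KASP-like): two allele-specific forward primers sharing a
   core, 3′-terminal base at the SNP, prefixed with the two universal
   fluorophore tails (FAM `GAAGGTGACCAAGTTCATGCT`, HEX
   `GAAGGTCGGAGTCAACGGATT`, read off the published primer sequences), plus
   one common reverse primer.

A "common" enzyme means membership in the bundled ~47-enzyme catalog;
catalog order encodes preference (cheap, ubiquitous cutters first) because
the source states no preference rule. The catalog ships with a provenance
note; user catalogs override and are never rewritten. One catalog entry
deserves mention: the published marker table prints "*BgI* I", which this
package reads as BglI (GCCNNNN^NGGC).

Whole-segment replacements far outside the indel window (a ~600-bp exon
replacement is the motivating case) can still be emitted as *structural*
markers: the cascade's last resort relaxes the amplicon ceiling (default
1500 bp) and attaches a warning note, since the published marker set itself
contains such an assay.

Primer picking (`design_primer_pair`) is written in-repo: lengths 18–24 nt,
Tm 52–62 °C (nearest-neighbor model at 50 mM Na⁺, 250 nM primer; Wallace
2(A+T)+4(G+C) below 14 nt), GC 35–65%, no mononucleotide run >4, no ≥4-bp
3′ cross-complementarity between partners. Selection is deterministic:
smallest amplicon, then highest minimum Tm, then leftmost forward primer.
Primer uniqueness is checked within the locus only — genome-wide
specificity screening is out of scope.

## In-silico assays

The primer-binding model is deliberately simple: a primer binds where its
3′-terminal base matches exactly and at most one other base mismatches.
That single rule makes engineered dCAPS primers bind (internal mismatch)
while PARMS allele-specific primers stay refractory on the wrong allele
(terminal mismatch). Products incorporate primer sequences, so a dCAPS
engineered base becomes a restriction site in the amplicon, as in real PCR.
Each forward site pairs with the nearest downstream reverse site within
5 kb. Amplification efficiency, heteroduplexes and primer-dimers are not
modelled.

Digestion is complete (every site cuts; overlapping sites all cut), only
top-strand cut positions matter, and fragments always sum to the amplicon
length. Two bands are distinguishable when they differ by at least the gel
resolution: 4 bp for PAGE (Indel, dCAPS), 20 bp for agarose (CAPS). The
published gel recipes imply but do not state resolutions; both thresholds
are config fields.

Two encoded fragment patterns in the transcribed marker table are gel-level
roundings rather than exact digests, and the package treats them as such by
comparing patterns at gel resolution: the ARE1 CAPS encoding's cut fragments
(100, 210) sum to 310 against a 320-bp amplicon (the realizable digest is
(100, 220)), and the NAC42 dCAPS primer's engineered DdeI site necessarily
cuts 17 bp from the amplicon's 5′ end, so the encoded (100, 20) is realized
as (103, 17). All other markers match their encodings exactly.

`validate_marker` passes a marker only if every non-n.d. accession calls
concordantly with its true haplotype and the two expected patterns are
separated at the applicable resolution. Genes addressed by two markers are
resolved jointly by set intersection over target-haplotype constraints; a
marker-based genotype can only name the classes its markers address, so
unresolved non-target classes are reported as "non-elite" (or a joint label
like "HapC/HapD"), never as an invented haplotype name.

## Scoring and elite maps

The default elite map counts HapB for every gene, plus HapC for ARE1 (two
distinct elite alleles exist for that gene). Whether the SBM1 HapD class — a
1.2-kb promoter deletion plus a start-codon-disrupting SNP, plausibly a
stronger loss-of-function than HapB — should count as elite is genuinely
ambiguous; it is excluded by default with a config toggle
(`default_elite_map(include_sbm1_hapd=True)`). n.d. calls never count.

The bundled 36-accession table keeps the source's printed per-accession
counts alongside the recomputed ones. Three rows disagree (the recomputed
count is one higher than printed for HZ, 9311 and Y58S); the package flags
them and treats the haplotype matrix itself as ground truth rather than
silently correcting either column. Group summaries aggregate at coarse
(XI/GJ/cA/cB) or fine (XI-1B, GJ-tmp, …) subpopulation level;
subpopulation labels are input metadata, never inferred.

## Synthetic fixtures: what they show

The generator plants SNP/indel haplotype profiles into seeded random loci
(default: 2-kb/1-kb flanks, a three-exon ~2.8-kb gene body, GC 0.44 to
approximate rice genic sequence) over inbred accessions, with canonical ATG
and stop codons at the gene-body boundaries. Planted variants may not
overlap; indels need ≥20 bp of clear flank so their aligned representation
is unambiguous (SNPs may sit closer, as real haplotypes do — one bundled
profile reproduces a published 14-SNP elite haplotype at its printed
positions). Reference context around planted indels is adjusted so planted
coordinates are already left-aligned, making recovery an exact equality
check.

Large seeded batches (the recovery tests and the acceptance script use 100
specs) run on a compact ~1.3-kb variant of the locus so a batch completes in
seconds; the variant-calling logic is length-independent, and the default
full-size locus is exercised by the per-module tests.

What passing these loops shows: alignment, calling, grouping, design and
assay simulation are mutually consistent and deterministic. What it does not
show: robustness to sequencing/assembly error, heterozygosity, segmental
duplication, reference bias, or PCR chemistry — none of which the generator
emulates. Likewise, the per-marker template loop validates the assay engine
against each transcribed marker's own specification, not against the
original genomes, which are not distributed with the article.

## Known limitations

* dCAPS engineering considers forward (top-strand) primers only.
* Primer specificity is locus-local; no genome-wide e-PCR.
* The gel model is a hard threshold; near-threshold size differences in
  reality give smeared, operator-dependent calls.
* Whole-collection summaries that depend on the original supplementary
  accession tables require those tables to be supplied as TSV; the loader
  (`scoring_report.score_panel_file`) then reproduces them in one command.
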