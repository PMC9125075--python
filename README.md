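# haplomark

Haplotype classification of candidate genes and design of intragenic
genotyping markers for marker-assisted selection, built around the workflow
used for nitrogen-use-efficiency (NUE) genes in Asian rice (*Oryza sativa*).

Rice breeders improving *geng*/*japonica* (GJ) cultivars want to introgress
the favourable ("elite") alleles of cloned NUE genes, most of which segregate
in *xian*/*indica* (XI) germplasm. That requires (1) classifying each gene's
haplotypes across a panel of sequenced accessions, (2) converting
haplotype-diagnostic variants into cheap PCR assays that co-segregate with
the allele because they lie inside the gene region itself, and (3) scoring
germplasm for how many elite haplotypes it carries. `haplomark` implements
that pipeline end to end, in silico.

## What it does

* **Region extraction** — for each gene, the analysed locus is a fixed
  window: a 2-kb flank upstream of the ATG ("5U"), the gene body through the
  stop codon, and a 1-kb downstream flank ("3U"). Minus-strand genes are
  reverse-complemented so all downstream logic is plus-oriented.
* **Haplotype analysis** — each accession locus is globally aligned to the
  reference accession (affine gaps: match +2, mismatch −3, gap open −5,
  extend −2 per base), variants are called at signed ATG-relative positions
  (+1 = A of ATG, −1 = the base 5′ of it, no zero) and left-aligned in
  repeats, and accessions with identical variant profiles form haplotypes:
  HapA is the reference profile, HapB the designated elite profile, the rest
  HapC, HapD, … by frequency. Accessions with unextractable sequence or more
  than 5 novel variants are "n.d." (not determined).
* **Marker design cascade** — variants private to the target haplotype(s)
  are turned into an assay by a strict priority: an **Indel** marker for a
  5–30 bp indel (100–300 bp amplicon, scored on PAGE); else a **CAPS**
  marker where a SNP naturally creates/destroys a common restriction site
  (100–500 bp amplicon, agarose); else a **dCAPS** marker whose primer
  carries ≤1 engineered mismatch near the 3′ end so one allele completes a
  site (100–300 bp); else a **PARMS** marker — two universally tailed
  allele-specific forward primers (FAM/HEX read-out) plus a common reverse.
  Markers are named `gene + region + type`, e.g. `NPF6.1 5U ID`,
  `SBM1 E3 S`.
* **In-silico assays** — virtual PCR (3′-exact binding, ≤1 internal
  mismatch), complete restriction digestion, a gel model (4 bp PAGE / 20 bp
  agarose resolution) and PARMS fluorophore calls, used both to validate
  designed markers against panels with known haplotypes and to genotype new
  panels.
* **Scoring** — per-accession elite-haplotype counts and per-gene,
  per-group carrier frequencies, with joint resolution of genes addressed
  by two markers (e.g. a CAPS targeting {HapB, HapD} plus an Indel targeting
  {HapB}).
* **Fixtures** — a seeded synthetic-panel generator (inbred accessions with
  planted haplotype profiles) plus transcriptions of the published
  36-accession × 14-gene haplotype matrix and the 18-marker table, shipped
  as data files.

## Worked example

Simulate a 20-accession panel with a planted elite haplotype, classify it,
and design a marker for HapB:

```sh
$ haplomark simulate --seed 3 --out sim
wrote 20-accession panel to sim

$ haplomark haplotype --panel sim/panel.fa --ref NIP --gene synthetic_gene
HapA    8 accessions    0 variants
HapB    8 accessions    4 variants
HapC    4 accessions    2 variants

$ haplomark design --panel sim/panel.fa --ref NIP --gene synthetic_gene \
      --targets HapB --out markers.tsv
synthetic_gene 5U ID    Indel   rule=indel
  F     ATAACAGAGTTCCGGTGCCTGACA
  R     AATACGGGGCATGGATCAATGGG

$ haplomark validate --markers markers.tsv --panel sim/panel.fa --truth haps.tsv
synthetic_gene 5U ID    PASS    8 alt / 12 ref
```

The panel carries three haplotypes: HapB (8 accessions) is defined by four
planted variants, one of which is a 20-bp promoter insertion; the cascade's
first rule fires and emits an Indel marker in the 5′ region (`5U ID`) whose
amplicon shifts by 20 bp in HapB carriers. Validation simulates the assay on
every accession: all 8 HapB accessions give the alternate band and the other
12 the reference band, so the marker fully separates the target haplotype.

Scoring the bundled 36-accession reference panel:

```sh
$ haplomark score --haps table2.tsv
36 accessions; elite count min 0 max 10 mean 5.67
```

Three XI accessions reach the maximum of 10 elite haplotypes out of 14 NUE
genes, while temperate GJ accessions carry none — the contrast that
motivates marker-assisted introgression into GJ backgrounds.

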