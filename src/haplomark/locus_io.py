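"""Readers/writers for panel sequences, gene models and enzyme catalogs, and
extraction of the analysed gene region.

The analysed region of a gene is a fixed window: a 2-kb flank upstream of the
start codon (called "5U" throughout, after the loose field usage), the genic
region from ATG through the stop codon, and a 1-kb downstream flank ("3U").
Equal windows across accessions are what make haplotypes comparable, so a
flank running off the contig is an error by default rather than a silent
clip.

Coordinates follow the GFF convention on input (1-based, inclusive); all
internal offsets are 0-based.  Minus-strand genes are reverse-complemented at
extraction time so downstream logic always sees a plus-oriented locus.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .enzyme_kit import IUPAC, Enzyme, revcomp

_VALID_BASES = set(IUPAC)


class FormatError(ValueError):
    """A file does not conform to its declared format."""


class BoundsError(ValueError):
    """A requested region runs off the available sequence."""


# ---------------------------------------------------------------------------
# gene models


@dataclass(frozen=True)
class GeneModel:
    """Gene structure on a genome or contig.

    ``atg_pos`` is the 1-based coordinate of the A of the start codon and
    ``stop_end`` the 1-based coordinate of the last base of the stop codon,
    both on the given strand (for '-' genes ``atg_pos > stop_end``).  Exons
    are 1-based inclusive intervals listed in transcription order.
    """

    gene_id: str
    seq_id: str
    strand: str
    atg_pos: int
    stop_end: int
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        exons = tuple((min(s, e), max(s, e)) for s, e in self.exons)
        if not exons:
            raise ValueError(f"{self.gene_id}: gene model needs >= 1 exon")
        ordered = exons if self.strand == "+" else exons[::-1]
        for (s1, e1), (s2, e2) in zip(ordered, ordered[1:]):
            if s2 <= e1:
                raise ValueError(f"{self.gene_id}: exons overlap or are unsorted")
        object.__setattr__(self, "exons", exons)
        first, last = self.exons[0], self.exons[-1]
        if not first[0] <= self.atg_pos <= first[1]:
            raise ValueError(f"{self.gene_id}: ATG not in the first exon")
        if not last[0] <= self.stop_end <= last[1]:
            raise ValueError(f"{self.gene_id}: stop codon not in the last exon")
        if self.strand == "+" and self.atg_pos >= self.stop_end:
            raise ValueError(f"{self.gene_id}: '+' gene needs atg_pos < stop_end")
        if self.strand == "-" and self.atg_pos <= self.stop_end:
            raise ValueError(f"{self.gene_id}: '-' gene needs atg_pos > stop_end")

    @property
    def genic_length(self) -> int:
        """ATG through stop codon, inclusive, in bp."""
        return abs(self.stop_end - self.atg_pos) + 1

    def atg_relative(self, genomic_pos: int) -> int:
        """Signed ATG-relative position of a genomic coordinate (no zero)."""
        d = (genomic_pos - self.atg_pos) if self.strand == "+" else (self.atg_pos - genomic_pos)
        return d + 1 if d >= 0 else d

    def exons_atg_relative(self) -> list[tuple[int, int]]:
        """Exon intervals as signed ATG-relative positions, transcription order."""
        out = []
        for s, e in self.exons:
            a, b = self.atg_relative(s), self.atg_relative(e)
            out.append((min(a, b), max(a, b)))
        return out


def read_gene_models(path: str | Path) -> dict[str, GeneModel]:
    """Read gene models from a simple TSV or a GFF3 file.

    The TSV has a header line ``gene_id seq_id strand atg_pos stop_end exons``
    with exons encoded ``start-end;start-end`` in transcription order.  GFF3
    input uses ``exon`` and ``CDS`` features grouped by their ``Parent`` (or
    ``ID``) attribute; the CDS span provides ATG and stop positions.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("##gff") or (first.count("\t") == 8 and not first.startswith("gene_id")):
        return _read_gff3(path)
    return _read_model_tsv(path)


def _read_model_tsv(path: Path) -> dict[str, GeneModel]:
    models: dict[str, GeneModel] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        expected = ["gene_id", "seq_id", "strand", "atg_pos", "stop_end", "exons"]
        if header != expected:
            raise FormatError(f"gene-model TSV header must be {expected}, got {header}")
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            gene_id, seq_id, strand, atg, stop, exons_s = line.rstrip("\n").split("\t")
            exons = tuple(
                tuple(int(x) for x in part.split("-")) for part in exons_s.split(";")
            )
            if gene_id in models:
                raise FormatError(f"duplicate gene_id {gene_id!r}")
            models[gene_id] = GeneModel(gene_id, seq_id, strand, int(atg), int(stop), exons)
    if not models:
        raise FormatError(f"{path}: no gene models found")
    return models


def _gff_attr(attrs: str, key: str) -> str | None:
    for part in attrs.rstrip(";").split(";"):
        if "=" in part:
            k, v = part.split("=", 1)
            if k.strip() == key:
                return v.strip()
    return None


def _read_gff3(path: Path) -> dict[str, GeneModel]:
    exons: dict[str, list[tuple[int, int]]] = {}
    cds: dict[str, list[tuple[int, int]]] = {}
    meta: dict[str, tuple[str, str]] = {}  # gene -> (seq_id, strand)
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) != 9:
                raise FormatError(f"{path}: GFF3 line with {len(cols)} columns")
            seq_id, _, ftype, start, end, _, strand, _, attrs = cols
            gene = _gff_attr(attrs, "Parent") or _gff_attr(attrs, "ID")
            if gene is None:
                continue
            gene = gene.split(".")[0]  # transcript ids fold onto the gene
            if ftype in ("exon", "CDS"):
                meta.setdefault(gene, (seq_id, strand))
                target = exons if ftype == "exon" else cds
                target.setdefault(gene, []).append((int(start), int(end)))
    models = {}
    for gene, (seq_id, strand) in meta.items():
        if gene not in cds:
            raise FormatError(f"{gene}: GFF3 input needs CDS features for ATG/stop")
        cds_lo = min(s for s, _ in cds[gene])
        cds_hi = max(e for _, e in cds[gene])
        atg, stop = (cds_lo, cds_hi) if strand == "+" else (cds_hi, cds_lo)
        ex = sorted(exons.get(gene, cds[gene]))
        if strand == "-":
            ex = ex[::-1]
        models[gene] = GeneModel(gene, seq_id, strand, atg, stop, tuple(ex))
    if not models:
        raise FormatError(f"{path}: no gene features found")
    return models


def write_gene_models(path: str | Path, models: Iterable[GeneModel]) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tseq_id\tstrand\tatg_pos\tstop_end\texons\n")
        for m in models:
            exons = ";".join(f"{s}-{e}" for s, e in m.exons)
            fh.write(f"{m.gene_id}\t{m.seq_id}\t{m.strand}\t{m.atg_pos}\t{m.stop_end}\t{exons}\n")


# ---------------------------------------------------------------------------
# locus sequences


@dataclass(frozen=True)
class LocusSequence:
    """A plus-oriented gene-region sequence for one accession.

    ``atg_offset`` is the 0-based index of the A of ATG within ``seq`` and
    ``stop_offset`` the index of the last stop-codon base; by construction
    ``atg_offset`` equals the upstream flank length.
    """

    accession: str
    gene_id: str
    seq: str
    atg_offset: int
    stop_offset: int
    source_interval: tuple[str, int, int, str] | None = None

    def __post_init__(self) -> None:
        seq = self.seq.upper()
        if not 0 <= self.atg_offset < self.stop_offset < len(seq):
            raise ValueError(
                f"{self.accession}/{self.gene_id}: need 0 <= atg_offset < "
                f"stop_offset < {len(seq)}"
            )
        bad = set(seq) - _VALID_BASES
        if bad:
            raise FormatError(f"{self.accession}: non-IUPAC characters {sorted(bad)}")
        object.__setattr__(self, "seq", seq)


def extract_locus(
    genome: str,
    model: GeneModel,
    upstream: int = 2000,
    downstream: int = 1000,
    accession: str = "ref",
    allow_truncation: bool = False,
) -> LocusSequence:
    """Cut the analysed region (upstream flank + genic region + downstream
    flank) out of ``genome`` and orient it to the plus strand.

    With ``allow_truncation`` a short contig produces a warning and a clipped
    flank instead of a :class:`BoundsError`; the actual flank lengths are then
    recorded in ``atg_offset``/``source_interval``.
    """
    n = len(genome)
    if model.strand == "+":
        lo = model.atg_pos - 1 - upstream
        hi = model.stop_end + downstream  # exclusive, 0-based
    else:
        lo = model.stop_end - 1 - downstream
        hi = model.atg_pos + upstream
    clipped_lo, clipped_hi = max(lo, 0), min(hi, n)
    if (lo < 0 or hi > n) and not allow_truncation:
        side_5 = "upstream" if model.strand == "+" else "downstream"
        side_3 = "downstream" if model.strand == "+" else "upstream"
        missing = []
        if lo < 0:
            missing.append(f"{side_5} flank short by {-lo} bp")
        if hi > n:
            missing.append(f"{side_3} flank short by {hi - n} bp")
        raise BoundsError(f"{model.gene_id}: " + "; ".join(missing))
    if (lo, hi) != (clipped_lo, clipped_hi):
        warnings.warn(
            f"{model.gene_id}: flank truncated to contig bounds "
            f"[{clipped_lo + 1}, {clipped_hi}]",
            stacklevel=2,
        )
    segment = genome[clipped_lo:clipped_hi].upper()
    if model.strand == "+":
        up_len = model.atg_pos - 1 - clipped_lo
    else:
        segment = revcomp(segment)
        up_len = clipped_hi - model.atg_pos
    return LocusSequence(
        accession=accession,
        gene_id=model.gene_id,
        seq=segment,
        atg_offset=up_len,
        stop_offset=up_len + model.genic_length - 1,
        source_interval=(model.seq_id, clipped_lo + 1, clipped_hi, model.strand),
    )


# ---------------------------------------------------------------------------
# FASTA panels


def read_panel_fasta(path: str | Path) -> dict[str, str]:
    """Read a panel FASTA into an accession -> sequence map.

    Sequences are uppercased; duplicate record ids, empty files and
    non-IUPAC characters are format errors.
    """
    panel: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in panel:
            raise FormatError(f"duplicate record id {record.id!r}")
        seq = str(record.seq).upper()
        bad = set(seq) - _VALID_BASES
        if bad:
            raise FormatError(f"{record.id}: non-IUPAC characters {sorted(bad)}")
        panel[record.id] = seq
    if not panel:
        raise FormatError(f"{path}: no FASTA records")
    return panel


def write_panel_fasta(path: str | Path, panel: dict[str, str]) -> None:
    records = [SeqRecord(Seq(seq), id=acc, description="") for acc, seq in panel.items()]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# enzyme catalogs


@dataclass
class EnzymeCatalog:
    """An ordered restriction-enzyme catalog; order encodes design preference."""

    entries: list[Enzyme] = field(default_factory=list)
    source: str = ""

    def __post_init__(self) -> None:
        names = [e.name for e in self.entries]
        if len(names) != len(set(names)):
            raise FormatError(f"{self.source}: duplicate enzyme names")

    def __iter__(self) -> Iterator[Enzyme]:
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    def get(self, name: str) -> Enzyme:
        for e in self.entries:
            if e.name == name:
                return e
        raise KeyError(f"enzyme {name!r} not in catalog {self.source or '<memory>'}")


def read_enzyme_catalog(path: str | Path) -> EnzymeCatalog:
    """Read a flat TSV catalog: name, IUPAC recognition, top-strand cut offset."""
    entries = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 3:
                raise FormatError(f"{path}:{lineno}: expected 3 columns, got {len(parts)}")
            name, recognition, offset = parts
            try:
                entries.append(Enzyme(name, recognition, int(offset)))
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return EnzymeCatalog(entries=entries, source=str(path))


def default_enzyme_catalog() -> EnzymeCatalog:
    """The bundled catalog of common commercial enzymes (BglI, TaqI, DdeI, ...)."""
    ref = resources.files("haplomark.data").joinpath("enzymes.tsv")
    with resources.as_file(ref) as path:
        catalog = read_enzyme_catalog(path)
    catalog.source = "bundled default"
    return catalog
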