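"""Panel evaluation: elite-haplotype counting and group summaries.

A germplasm panel is scored against an elite map (gene -> elite haplotype
names).  By default every gene's elite class is HapB — the reported elite
haplotype, with the reference accession's class being HapA — except ARE1,
where two distinct elite alleles exist and both HapB and HapC count.
Whether the SBM1 HapD class (a likely loss-of-function start-codon variant)
should count as elite is genuinely ambiguous; it is excluded by default and
available as a toggle.

n.d. (not determined) calls never count as elite.  Marker-based haplotyping
can only resolve the classes its markers address, so unresolved non-target
classes are reported as the honest label "non-elite" (or a joint label such
as "HapC/HapD") rather than an invented haplotype name.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .marker_design import MarkerAssay

ND = "n.d."
NON_ELITE = "non-elite"

#: The 14 cloned nitrogen-use-efficiency genes, in the panel table's order.
GENES = [
    "OsNPF6.1", "DNR1", "MYB61", "SBM1", "NGR2", "OsNR2", "NGR5",
    "OsTCP19", "ARE1", "DEP1", "OsNAC42", "OsNLP4", "NRT1.1B", "TOND1",
]


def default_elite_map(include_sbm1_hapd: bool = False) -> dict[str, set[str]]:
    """gene -> elite haplotype names; HapB everywhere, plus ARE1 HapC."""
    elite = {gene: {"HapB"} for gene in GENES}
    elite["ARE1"] = {"HapB", "HapC"}
    if include_sbm1_hapd:
        elite["SBM1"] = {"HapB", "HapD"}
    return elite


def count_elite(calls: dict[str, str], elite: dict[str, set[str]]) -> int:
    """Number of genes whose haplotype call is elite; n.d. contributes 0."""
    total = 0
    for gene, call in calls.items():
        if gene not in elite:
            raise KeyError(f"gene {gene!r} absent from the elite map")
        if call != ND and call in elite[gene]:
            total += 1
    return total


# ---------------------------------------------------------------------------
# haplotype tables (panel x gene matrices)


@dataclass
class HaplotypeTable:
    """An accession x gene haplotype matrix with panel metadata.

    ``calls`` holds plain haplotype names (or ``n.d.``); ``flagged`` marks
    entries the source printed as elite (bold); ``printed_counts`` keeps the
    source's own per-accession count column, when present, alongside the
    recomputed one so discrepancies stay visible.
    """

    calls: pd.DataFrame  # index accession, columns GENES
    groups: pd.Series  # accession -> subpopulation label
    origins: pd.Series
    flagged: pd.DataFrame | None = None
    printed_counts: pd.Series | None = None

    @property
    def accessions(self) -> list[str]:
        return list(self.calls.index)


def read_haplotype_table(path: str | Path) -> HaplotypeTable:
    """Read a panel table: accession, origin, subpopulation, one column per
    gene (a trailing ``*`` flags a source-bold entry), and optionally a
    ``printed_count`` column."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str).set_index("accession")
    gene_cols = [c for c in df.columns if c not in ("origin", "subpopulation", "printed_count")]
    calls = df[gene_cols].map(lambda s: s.rstrip("*"))
    flagged = df[gene_cols].map(lambda s: s.endswith("*"))
    printed = None
    if "printed_count" in df.columns:
        printed = df["printed_count"].astype(int)
    return HaplotypeTable(
        calls=calls,
        groups=df["subpopulation"],
        origins=df.get("origin", pd.Series("", index=df.index)),
        flagged=flagged,
        printed_counts=printed,
    )


def write_haplotype_table(path: str | Path, table: HaplotypeTable) -> None:
    out = table.calls.copy()
    if table.flagged is not None:
        for col in out.columns:
            out[col] = [
                v + "*" if f else v
                for v, f in zip(out[col], table.flagged[col])
            ]
    out.insert(0, "subpopulation", table.groups)
    out.insert(0, "origin", table.origins)
    if table.printed_counts is not None:
        out["printed_count"] = table.printed_counts
    out.index.name = "accession"
    out.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# score reports


@dataclass
class ScoreReport:
    """Per-accession haplotype calls with recomputed elite counts."""

    rows: pd.DataFrame  # group, per-gene calls, elite_count (+ printed_count)
    elite: dict[str, set[str]]

    @property
    def elite_counts(self) -> pd.Series:
        return self.rows["elite_count"]

    def count_discrepancies(self) -> list[str]:
        """Accessions whose recomputed count disagrees with the printed one."""
        if "printed_count" not in self.rows.columns:
            return []
        mask = self.rows["elite_count"] != self.rows["printed_count"]
        return list(self.rows.index[mask])


def score_table(table: HaplotypeTable, elite: dict[str, set[str]] | None = None) -> ScoreReport:
    elite = elite or default_elite_map()
    counts = [
        count_elite(dict(row), elite) for _, row in table.calls.iterrows()
    ]
    rows = table.calls.copy()
    rows.insert(0, "group", table.groups)
    rows["elite_count"] = counts
    if table.printed_counts is not None:
        rows["printed_count"] = table.printed_counts
    return ScoreReport(rows=rows, elite=elite)


def coarse_group(subpopulation: str) -> str:
    """XI-1B -> XI, GJ-tmp -> GJ; cA/cB and other labels pass through."""
    return subpopulation.split("-")[0]


def summarize_by_group(
    report: ScoreReport, level: str = "coarse"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-gene, per-group elite-carrier counts/frequencies, and per-group
    min/max/mean of the elite count.  Empty groups yield zero rows."""
    rows = report.rows
    groups = rows["group"] if level == "fine" else rows["group"].map(coarse_group)
    gene_cols = [c for c in rows.columns
                 if c not in ("group", "elite_count", "printed_count")]
    records = []
    for gname, idx in rows.groupby(groups).groups.items():
        sub = rows.loc[idx]
        n = len(sub)
        for gene in gene_cols:
            carriers = int(sub[gene].isin(report.elite[gene]).sum())
            records.append({
                "group": gname, "gene": gene, "n_accessions": n,
                "elite_carriers": carriers,
                "frequency": carriers / n if n else 0.0,
            })
    carriers = pd.DataFrame.from_records(records)
    stats = (
        rows.assign(group=groups)
        .groupby("group")["elite_count"]
        .agg(["min", "max", "mean", "count"])
    )
    return carriers, stats


# ---------------------------------------------------------------------------
# marker calls -> per-gene haplotype labels


def genotype_to_haplotype(
    band_calls: dict[str, str], markers: list[MarkerAssay]
) -> dict[str, str]:
    """Resolve per-marker allele-class calls into per-gene haplotype labels.

    alt_class on a marker narrows the gene to that marker's target
    haplotypes; ref_class excludes them.  Two markers on one gene resolve
    jointly (e.g. a CAPS targeting {HapB, HapD} plus an Indel targeting
    {HapB} separates HapB from HapD).  Any null or ambiguous band, or
    mutually conflicting calls, gives n.d. for that gene.
    """
    by_gene: dict[str, list[MarkerAssay]] = {}
    for marker in markers:
        by_gene.setdefault(marker.gene_id, []).append(marker)
    out: dict[str, str] = {}
    for gene, gene_markers in by_gene.items():
        universe: set[str] = {NON_ELITE}
        for m in gene_markers:
            universe |= set(m.target_haplotypes)
        candidates = set(universe)
        bad = False
        for m in gene_markers:
            call = band_calls.get(m.name)
            if call in (None, "null", "ambiguous"):
                bad = True
                break
            targets = set(m.target_haplotypes)
            if call == "alt_class":
                candidates &= targets
            elif call == "ref_class":
                candidates -= targets
            else:
                raise ValueError(f"unknown band call {call!r} for {m.name}")
        if bad or not candidates:
            out[gene] = ND
        elif candidates == {NON_ELITE}:
            out[gene] = NON_ELITE
        elif len(candidates) == 1:
            out[gene] = candidates.pop()
        else:
            out[gene] = "/".join(sorted(candidates - {NON_ELITE}))
    return out


def score_marker_panel(
    panel_calls: dict[str, dict[str, str]],
    markers: list[MarkerAssay],
    groups: dict[str, str],
    elite: dict[str, set[str]] | None = None,
) -> ScoreReport:
    """Score a panel genotyped with markers: accession -> marker-name calls.

    Joint labels (``HapC/HapD``) count as elite only when every constituent
    is elite for that gene.
    """
    genes = sorted({m.gene_id for m in markers})
    elite = elite or {g: default_elite_map().get(g, {"HapB"}) for g in genes}
    records = {}
    for accession, calls in panel_calls.items():
        gene_calls = genotype_to_haplotype(calls, markers)
        resolved = {}
        for gene, label in gene_calls.items():
            if "/" in label:
                parts = set(label.split("/"))
                resolved[gene] = label if parts <= elite[gene] else NON_ELITE
            else:
                resolved[gene] = label
        n_elite = sum(
            1 for gene, label in resolved.items()
            if label != ND and (label in elite[gene] or
                                ("/" in label and set(label.split("/")) <= elite[gene]))
        )
        records[accession] = {
            "group": groups.get(accession, ""), **gene_calls, "elite_count": n_elite
        }
    rows = pd.DataFrame.from_dict(records, orient="index")
    rows.index.name = "accession"
    return ScoreReport(rows=rows, elite=elite)


def score_panel_file(path: str | Path, elite: dict[str, set[str]] | None = None) -> ScoreReport:
    """One-command scoring of a panel haplotype table supplied as TSV (the
    format mirrors the published panel tables, so a supplementary panel
    table transcribed to TSV scores directly)."""
    return score_table(read_haplotype_table(path), elite)


def plot_distribution(report: ScoreReport, path: str | Path, level: str = "coarse") -> None:
    """Stacked-bar plot of per-gene elite-carrier frequencies by group."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    carriers, _ = summarize_by_group(report, level=level)
    pivot = carriers.pivot(index="gene", columns="group", values="frequency")
    ax = pivot.plot.bar(figsize=(10, 4))
    ax.set_ylabel("elite-haplotype frequency")
    ax.figure.tight_layout()
    ax.figure.savefig(path)
    plt.close(ax.figure)
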