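"""Readers and writers for the external table and sequence formats the pipeline touches.

Internal genomic coordinates are always 0-based half-open (BED convention).
CIRI reports 1-based inclusive coordinates and is converted on read; the
CIRCexplorer2 "annotate" dialect is already BED-like and passes through
unchanged.  A back-splice junction is keyed by ``chrom:start-end:strand`` —
strand is part of the key because back-splicing is strand-specific.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "CircRecord",
    "InteractionTableRow",
    "read_circexplorer2",
    "write_circexplorer2",
    "read_ciri",
    "merge_conditions",
    "read_4dgenome",
    "write_4dgenome",
    "write_merged_table",
    "read_merged_table",
]

_STRANDS = {"+", "-"}

CIRCEXPLORER2_COLUMNS = [
    "chrom", "start", "end", "name", "score", "strand", "thickStart",
    "thickEnd", "itemRgb", "exonCount", "exonSizes", "exonOffsets",
    "readNumber", "circType", "geneName", "isoformName", "index",
    "flankIntron",
]

CIRI_COLUMNS = [
    "circRNA_ID", "chr", "circRNA_start", "circRNA_end", "#junction_reads",
    "SM_MS_SMS", "#non_junction_reads", "junction_reads_ratio",
    "circRNA_type", "gene_id", "strand",
]

FOURDGENOME_COLUMNS = [
    "InteractorAChr", "InteractorAStart", "InteractorAEnd",
    "InteractorBChr", "InteractorBStart", "InteractorBEnd",
    "Agene", "Bgene", "Cell/Tissue", "Detection_Method",
    "Confidence_Score1", "Confidence_Score2", "Contact_Frequency",
    "Organism",
]

MERGED_COLUMNS = [
    "circ_key", "gene_symbol", "gene_id", "db_id", "chrom", "start", "end",
    "strand", "exon_indices", "exon_count", "reads_control", "reads_treated",
    "intron5_interval", "intron3_interval",
]


@dataclass
class CircRecord:
    """One back-splice junction call.

    ``reads_control``/``reads_treated`` hold per-condition junction read
    counts; before :func:`merge_conditions` only the slot of the condition
    the file was read for is populated (the other is 0).
    """

    chrom: str
    start: int
    end: int
    strand: str
    gene_symbol: str = ""
    gene_id: str = ""
    db_id: str = ""
    exon_indices: tuple[int, ...] = field(default_factory=tuple)
    reads_control: int = 0
    reads_treated: int = 0
    intron5_interval: tuple[str, int, int] | None = None
    intron3_interval: tuple[str, int, int] | None = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: start must be < end"
            )
        if self.strand not in _STRANDS:
            raise ValueError(f"unknown strand symbol {self.strand!r}")

    @property
    def circ_key(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}:{self.strand}"

    @property
    def exon_count(self) -> int:
        return len(self.exon_indices)

    @property
    def genomic_length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class InteractionTableRow:
    """One chromatin long-range interaction, one (gene_a, gene_b) pair per row."""

    chrom_a: str
    start_a: int
    end_a: int
    chrom_b: str
    start_b: int
    end_b: int
    gene_a: str
    gene_b: str
    method: str

    def __post_init__(self) -> None:
        if self.start_a >= self.end_a or self.start_b >= self.end_b:
            raise ValueError("interaction interval has start >= end")


def _format_flank(interval: tuple[str, int, int] | None) -> str:
    if interval is None:
        return "None"
    return f"{interval[0]}:{interval[1]}-{interval[2]}"


def _parse_flank(text: str) -> tuple[str, int, int] | None:
    text = text.strip()
    if not text or text == "None":
        return None
    chrom, _, span = text.partition(":")
    lo, _, hi = span.partition("-")
    return (chrom, int(lo), int(hi))


def read_circexplorer2(path: str | Path, condition: str = "treated") -> list[CircRecord]:
    """Read a CIRCexplorer2 ``annotate`` table into :class:`CircRecord` s.

    ``condition`` ("control" or "treated") names the read-count slot the
    file's junction-read column is mapped to.
    """
    if condition not in ("control", "treated"):
        raise ValueError(f"condition must be 'control' or 'treated', got {condition!r}")
    records: list[CircRecord] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != len(CIRCEXPLORER2_COLUMNS):
                raise ValueError(
                    f"{path}: line {lineno}: expected "
                    f"{len(CIRCEXPLORER2_COLUMNS)} tab-separated fields, got {len(fields)}"
                )
            row = dict(zip(CIRCEXPLORER2_COLUMNS, fields))
            try:
                reads = int(row["readNumber"])
                exon_indices = tuple(
                    int(x) for x in row["index"].split(",") if x.strip() != ""
                )
                flank = row["flankIntron"]
                if "|" in flank:
                    f5_text, f3_text = flank.split("|", 1)
                else:
                    f5_text = f3_text = "None"
                record = CircRecord(
                    chrom=row["chrom"],
                    start=int(row["start"]),
                    end=int(row["end"]),
                    strand=row["strand"],
                    gene_symbol=row["geneName"],
                    exon_indices=exon_indices,
                    intron5_interval=_parse_flank(f5_text),
                    intron3_interval=_parse_flank(f3_text),
                )
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from exc
            if condition == "control":
                record.reads_control = reads
            else:
                record.reads_treated = reads
            records.append(record)
    return records


def write_circexplorer2(
    records: Iterable[CircRecord], path: str | Path, condition: str = "treated"
) -> None:
    """Serialize records in the CIRCexplorer2 ``annotate`` dialect."""
    with open(path, "w", newline="") as fh:
        for rec in records:
            reads = rec.reads_control if condition == "control" else rec.reads_treated
            n_exon = rec.exon_count
            if rec.intron5_interval is None and rec.intron3_interval is None:
                flank = "None"
            else:
                flank = f"{_format_flank(rec.intron5_interval)}|{_format_flank(rec.intron3_interval)}"
            fields = [
                rec.chrom, str(rec.start), str(rec.end),
                f"circular_RNA/{rec.circ_key}", "0", rec.strand,
                str(rec.start), str(rec.end), "0,0,0", str(n_exon),
                ",".join("100" for _ in range(n_exon)) or "0",
                ",".join("0" for _ in range(n_exon)) or "0",
                str(reads), "circRNA", rec.gene_symbol,
                rec.gene_id or "NA", ",".join(str(i) for i in rec.exon_indices),
                flank,
            ]
            fh.write("\t".join(fields) + "\n")


def read_ciri(path: str | Path, condition: str = "treated") -> list[CircRecord]:
    """Read a CIRI v2 table; 1-based inclusive coordinates become 0-based half-open."""
    if condition not in ("control", "treated"):
        raise ValueError(f"condition must be 'control' or 'treated', got {condition!r}")
    records: list[CircRecord] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if not header.startswith("circRNA_ID"):
            raise ValueError(f"{path}: missing CIRI header (must begin 'circRNA_ID')")
        cols = header.split("\t")
        for lineno, raw in enumerate(fh, start=2):
            line = raw.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            row = dict(zip(cols, fields))
            start = int(row["circRNA_start"]) - 1  # 1-based inclusive -> 0-based
            end = int(row["circRNA_end"])
            if start < 0:
                raise ValueError(
                    f"{path}: line {lineno}: negative coordinate after 1-based conversion"
                )
            record = CircRecord(
                chrom=row["chr"],
                start=start,
                end=end,
                strand=row["strand"],
                gene_id=row.get("gene_id", ""),
            )
            reads = int(row["#junction_reads"])
            if condition == "control":
                record.reads_control = reads
            else:
                record.reads_treated = reads
            records.append(record)
    return records


def merge_conditions(
    control: Sequence[CircRecord], treated: Sequence[CircRecord]
) -> list[CircRecord]:
    """Intersect two per-condition call sets on circ_key, filling both read slots.

    Mirrors the spreadsheet-lookup step that produced the shared circRNA list:
    only junctions called in *both* conditions survive.  Output is sorted by
    circ_key for determinism.
    """
    by_key: dict[str, CircRecord] = {}
    for rec in control:
        if rec.circ_key in by_key:
            raise ValueError(f"duplicate circ_key in control condition: {rec.circ_key}")
        by_key[rec.circ_key] = rec
    merged: list[CircRecord] = []
    seen_treated: set[str] = set()
    for rec in treated:
        if rec.circ_key in seen_treated:
            raise ValueError(f"duplicate circ_key in treated condition: {rec.circ_key}")
        seen_treated.add(rec.circ_key)
        ctrl = by_key.get(rec.circ_key)
        if ctrl is None:
            continue
        out = replace(
            ctrl,
            reads_control=ctrl.reads_control,
            reads_treated=rec.reads_treated,
        )
        # prefer annotation fields from whichever side has them
        if not out.gene_symbol:
            out.gene_symbol = rec.gene_symbol
        if not out.gene_id:
            out.gene_id = rec.gene_id
        if not out.exon_indices:
            out.exon_indices = rec.exon_indices
        if out.intron5_interval is None:
            out.intron5_interval = rec.intron5_interval
        if out.intron3_interval is None:
            out.intron3_interval = rec.intron3_interval
        merged.append(out)
    merged.sort(key=lambda r: r.circ_key)
    return merged


def read_4dgenome(path: str | Path) -> list[InteractionTableRow]:
    """Read a 4DGenome-schema interaction table.

    Multi-gene interactor fields (``;``-separated) are expanded into one row
    per (gene_a, gene_b) pair.  Trans-chromosomal rows are retained here;
    distance computation excludes them later.
    """
    rows: list[InteractionTableRow] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) != len(FOURDGENOME_COLUMNS):
            raise ValueError(
                f"{path}: expected {len(FOURDGENOME_COLUMNS)} columns, got "
                f"{len(header)}: {header!r}"
            )
        for lineno, raw in enumerate(fh, start=2):
            line = raw.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != len(FOURDGENOME_COLUMNS):
                raise ValueError(
                    f"{path}: line {lineno}: expected {len(FOURDGENOME_COLUMNS)} "
                    f"columns, got {len(fields)}: header {header!r}"
                )
            row = dict(zip(FOURDGENOME_COLUMNS, fields))
            genes_a = [g for g in row["Agene"].split(";") if g] or [""]
            genes_b = [g for g in row["Bgene"].split(";") if g] or [""]
            for ga in genes_a:
                for gb in genes_b:
                    rows.append(
                        InteractionTableRow(
                            chrom_a=row["InteractorAChr"],
                            start_a=int(row["InteractorAStart"]),
                            end_a=int(row["InteractorAEnd"]),
                            chrom_b=row["InteractorBChr"],
                            start_b=int(row["InteractorBStart"]),
                            end_b=int(row["InteractorBEnd"]),
                            gene_a=ga,
                            gene_b=gb,
                            method=row["Detection_Method"],
                        )
                    )
    return rows


def write_4dgenome(rows: Iterable[InteractionTableRow], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        fh.write("\t".join(FOURDGENOME_COLUMNS) + "\n")
        for r in rows:
            fh.write(
                "\t".join(
                    [
                        r.chrom_a, str(r.start_a), str(r.end_a),
                        r.chrom_b, str(r.start_b), str(r.end_b),
                        r.gene_a, r.gene_b, "synthetic", r.method,
                        "1", "1", "1", "Homo sapiens",
                    ]
                )
                + "\n"
            )


def write_merged_table(records: Iterable[CircRecord], path: str | Path) -> None:
    """Export a merged two-condition table as TSV with a fixed header."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(MERGED_COLUMNS)
        for rec in records:
            writer.writerow(
                [
                    rec.circ_key, rec.gene_symbol, rec.gene_id, rec.db_id,
                    rec.chrom, rec.start, rec.end, rec.strand,
                    ",".join(str(i) for i in rec.exon_indices), rec.exon_count,
                    rec.reads_control, rec.reads_treated,
                    _format_flank(rec.intron5_interval),
                    _format_flank(rec.intron3_interval),
                ]
            )


def read_merged_table(path: str | Path) -> list[CircRecord]:
    records: list[CircRecord] = []
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            records.append(
                CircRecord(
                    chrom=row["chrom"],
                    start=int(row["start"]),
                    end=int(row["end"]),
                    strand=row["strand"],
                    gene_symbol=row["gene_symbol"],
                    gene_id=row["gene_id"],
                    db_id=row["db_id"],
                    exon_indices=tuple(
                        int(x) for x in row["exon_indices"].split(",") if x
                    ),
                    reads_control=int(row["reads_control"]),
                    reads_treated=int(row["reads_treated"]),
                    intron5_interval=_parse_flank(row["intron5_interval"]),
                    intron3_interval=_parse_flank(row["intron3_interval"]),
                )
            )
    return records
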