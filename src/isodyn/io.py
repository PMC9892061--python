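"""Readers and writers for the flat genomic formats the pipeline touches.

Conventions at the boundary: GTF is 1-based inclusive and converted to the
internal 0-based half-open system on read/write; BED and bedGraph pass
through unchanged (already 0-based half-open).  Writers emit deterministic
line order (chrom, start, id).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import pandas as pd
from Bio import SeqIO

from .models import (
    Annotation,
    CoverageTrack,
    DataError,
    GenomeSequence,
    TranscriptModel,
)


class ParseError(DataError):
    def __init__(self, path, lineno: int, message: str):
        super().__init__(f"{path}:{lineno}: {message}")
        self.path = str(path)
        self.lineno = lineno


_GTF_ATTR = re.compile(r'(\w+)\s+"([^"]*)"')


def read_annotation(path, dialect: str = "gtf") -> Annotation:
    """Parse transcript models from the exon records of a GTF file."""
    if dialect != "gtf":
        raise DataError(f"unsupported dialect {dialect!r}")
    exons: Dict[str, List[Tuple[int, int]]] = {}
    meta: Dict[str, Tuple[str, str, str]] = {}  # tid -> (gene_id, chrom, strand)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 9:
                raise ParseError(path, lineno, f"expected 9 columns, got {len(fields)}")
            chrom, _source, feature, start_s, end_s, _score, strand, _frame, attrs = fields[:9]
            if feature != "exon":
                continue
            try:
                start = int(start_s)
                end = int(end_s)
            except ValueError:
                raise ParseError(path, lineno, f"non-numeric coordinate {start_s!r}/{end_s!r}")
            if end < start:
                raise ParseError(path, lineno, f"end < start ({end} < {start})")
            attr = dict(_GTF_ATTR.findall(attrs))
            if "gene_id" not in attr or "transcript_id" not in attr:
                raise ParseError(path, lineno, "missing gene_id or transcript_id attribute")
            tid = attr["transcript_id"]
            if tid not in meta:
                meta[tid] = (attr["gene_id"], chrom, strand)
            exons.setdefault(tid, []).append((start - 1, end))  # to 0-based half-open
    models = []
    for tid in sorted(exons):
        gene_id, chrom, strand = meta[tid]
        models.append(
            TranscriptModel(
                transcript_id=tid,
                gene_id=gene_id,
                chrom=chrom,
                strand=strand,
                exons=tuple(sorted(exons[tid])),
            )
        )
    return Annotation(models)


def write_annotation(annotation: Annotation, path, source: str = "isodyn") -> None:
    records = sorted(
        annotation.transcripts.values(),
        key=lambda t: (t.chrom, t.start, t.transcript_id),
    )
    with open(path, "w") as fh:
        for t in records:
            attrs = f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}";'
            fh.write(
                f"{t.chrom}\t{source}\ttranscript\t{t.start + 1}\t{t.end}\t.\t"
                f"{t.strand}\t.\t{attrs}\n"
            )
            for (s, e) in t.exons:
                fh.write(
                    f"{t.chrom}\t{source}\texon\t{s + 1}\t{e}\t.\t{t.strand}\t.\t{attrs}\n"
                )


@dataclass(frozen=True)
class BedRecord:
    chrom: str
    start: int
    end: int
    name: str = "."
    score: float = 0.0
    strand: str = "."  # '.' means unstranded

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


def read_intervals(path) -> List[BedRecord]:
    """Read BED3/BED6 records; missing strand -> unstranded, missing score -> 0."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(path, lineno, f"expected >=3 columns, got {len(fields)}")
            try:
                start = int(fields[1])
                end = int(fields[2])
            except ValueError:
                raise ParseError(path, lineno, "non-numeric coordinate")
            if end < start:
                raise ParseError(path, lineno, f"end < start ({end} < {start})")
            name = fields[3] if len(fields) > 3 else "."
            try:
                score = float(fields[4]) if len(fields) > 4 and fields[4] != "." else 0.0
            except ValueError:
                raise ParseError(path, lineno, f"non-numeric score {fields[4]!r}")
            strand = fields[5] if len(fields) > 5 else "."
            if strand not in ("+", "-", "."):
                raise ParseError(path, lineno, f"bad strand {strand!r}")
            out.append(BedRecord(fields[0], start, end, name, score, strand))
    return out


def write_intervals(records: Sequence[BedRecord], path) -> None:
    ordered = sorted(records, key=lambda r: (r.chrom, r.start, r.end, r.name))
    with open(path, "w") as fh:
        for r in ordered:
            score = int(r.score) if float(r.score).is_integer() else r.score
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.name}\t{score}\t{r.strand}\n")


def read_coverage(path) -> CoverageTrack:
    """Read a bedGraph file into a CoverageTrack (gaps read as depth 0)."""
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ParseError(path, lineno, f"expected 4 columns, got {len(fields)}")
            try:
                start = int(fields[1])
                end = int(fields[2])
                depth = float(fields[3])
            except ValueError:
                raise ParseError(path, lineno, "non-numeric coordinate or depth")
            if depth < 0:
                raise ParseError(path, lineno, f"negative depth {depth}")
            intervals.append((fields[0], start, end, depth))
    try:
        return CoverageTrack.from_intervals(intervals)
    except DataError as exc:
        raise DataError(f"{path}: {exc}") from exc


def write_coverage(track: CoverageTrack, path) -> None:
    with open(path, "w") as fh:
        for chrom in track.chromosomes():
            for (s, e, d) in track.intervals(chrom):
                val = int(d) if float(d).is_integer() else d
                fh.write(f"{chrom}\t{s}\t{e}\t{val}\n")


def read_genome(path) -> GenomeSequence:
    seqs: Dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in seqs:
            raise DataError(f"{path}: duplicate sequence name {record.id!r}")
        seqs[record.id] = str(record.seq)
    return GenomeSequence(seqs)


def write_genome(genome: GenomeSequence, path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for chrom in genome.chromosomes():
            seq = genome.fetch(chrom, 0, genome.lengths[chrom])
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


# --- tab-separated tables with declared schemas -------------------------------

FLNC_COUNT_COLUMNS = ["transcript_id", "gene_id", "sample", "count"]
JUNCTION_COUNT_COLUMNS = ["chrom", "start", "end", "strand", "count", "sample"]
GENE_EXPRESSION_COLUMNS = ["gene_id"]  # plus one fpkm column per condition


def read_table(path, required_columns: Sequence[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in required_columns if c not in df.columns]
    if missing:
        raise DataError(f"{path}: missing required column(s) {missing}")
    return df


def read_flnc_counts(path) -> pd.DataFrame:
    df = read_table(path, FLNC_COUNT_COLUMNS)
    df["count"] = df["count"].astype(int)
    return df


def read_junction_counts(path) -> pd.DataFrame:
    df = read_table(path, JUNCTION_COUNT_COLUMNS)
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    df["count"] = df["count"].astype(int)
    return df


def read_tpm(path, samples: Optional[Sequence[str]] = None) -> pd.DataFrame:
    """Transcript x sample TPM matrix, indexed by transcript_id."""
    df = read_table(path, ["transcript_id"])
    df = df.set_index("transcript_id")
    if samples is not None:
        missing = [s for s in samples if s not in df.columns]
        if missing:
            raise DataError(f"{path}: missing sample column(s) {missing}")
    return df


def write_table(df: pd.DataFrame, path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)
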