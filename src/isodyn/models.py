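"""Core domain types for transcript-level analysis.

All genomic coordinates are 0-based half-open on the forward genome strand.
Strand-aware notions (TSS, PAS, donor/acceptor, first intron) are derived
from the strand field, never stored redundantly.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, List, Optional, Sequence, Tuple

import numpy as np

Interval = Tuple[int, int]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class IsodynError(Exception):
    """Base class for package errors."""


class DataError(IsodynError):
    """Malformed or inconsistent input data."""


class GenomeSequence:
    """Uppercase per-chromosome nucleotide sequences with bounds-checked access."""

    def __init__(self, sequences: Dict[str, str]):
        self._seq: Dict[str, str] = {}
        for name, seq in sequences.items():
            if name in self._seq:
                raise DataError(f"duplicate sequence name {name!r}")
            self._seq[name] = seq.upper()

    @property
    def lengths(self) -> Dict[str, int]:
        return {name: len(seq) for name, seq in self._seq.items()}

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._seq

    def chromosomes(self) -> List[str]:
        return sorted(self._seq)

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Return sequence of [start, end); positions outside [0, length) are rejected."""
        if chrom not in self._seq:
            raise DataError(f"unknown chromosome {chrom!r}")
        n = len(self._seq[chrom])
        if start < 0 or end > n or start > end:
            raise DataError(
                f"interval [{start}, {end}) outside chromosome {chrom} bounds [0, {n})"
            )
        return self._seq[chrom][start:end]

    def fetch_clamped(self, chrom: str, start: int, end: int) -> str:
        """Like fetch, but truncates the interval at chromosome edges."""
        if chrom not in self._seq:
            raise DataError(f"unknown chromosome {chrom!r}")
        n = len(self._seq[chrom])
        return self._seq[chrom][max(0, start):min(n, end)]


@dataclass(frozen=True)
class TranscriptModel:
    """Strand-aware exon-chain representation of one isoform.

    Exons are sorted left-to-right on the genome regardless of strand; the
    TSS is the leftmost coordinate on '+' and the rightmost on '-', the PAS
    the opposite end.  The junction chain is the ordered list of intron
    intervals (empty for mono-exon models).
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: Tuple[Interval, ...]

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise DataError(f"{self.transcript_id}: strand must be '+' or '-'")
        if not self.exons:
            raise DataError(f"{self.transcript_id}: no exons")
        exons = tuple((int(s), int(e)) for s, e in self.exons)
        object.__setattr__(self, "exons", exons)
        prev_end = None
        for s, e in exons:
            if e <= s:
                raise DataError(f"{self.transcript_id}: empty or inverted exon [{s}, {e})")
            if prev_end is not None and s < prev_end:
                raise DataError(f"{self.transcript_id}: exons overlap or are unsorted")
            prev_end = e

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end

    @property
    def pas(self) -> int:
        return self.end if self.strand == "+" else self.start

    @property
    def introns(self) -> Tuple[Interval, ...]:
        return tuple(
            (self.exons[i][1], self.exons[i + 1][0]) for i in range(len(self.exons) - 1)
        )

    @property
    def is_multi_exon(self) -> bool:
        return len(self.exons) > 1

    @property
    def first_intron(self) -> Optional[Interval]:
        """Intron nearest the TSS, or None for mono-exon models."""
        introns = self.introns
        if not introns:
            return None
        return introns[0] if self.strand == "+" else introns[-1]

    @property
    def last_intron(self) -> Optional[Interval]:
        introns = self.introns
        if not introns:
            return None
        return introns[-1] if self.strand == "+" else introns[0]

    @property
    def terminal_exon(self) -> Interval:
        """The 3'-most exon along the transcript (strand-aware)."""
        return self.exons[-1] if self.strand == "+" else self.exons[0]

    @property
    def first_exon(self) -> Interval:
        return self.exons[0] if self.strand == "+" else self.exons[-1]


class Annotation:
    """A catalog of transcript models with gene, junction and splice-site indexes."""

    def __init__(self, transcripts: Iterable[TranscriptModel]):
        self.transcripts: Dict[str, TranscriptModel] = {}
        self.genes: Dict[str, List[str]] = {}
        for t in transcripts:
            if t.transcript_id in self.transcripts:
                raise DataError(f"duplicate transcript id {t.transcript_id!r}")
            self.transcripts[t.transcript_id] = t
            self.genes.setdefault(t.gene_id, []).append(t.transcript_id)
        for ids in self.genes.values():
            ids.sort()
        self._indexes_built = False

    def __len__(self) -> int:
        return len(self.transcripts)

    def __iter__(self) -> Iterator[TranscriptModel]:
        return iter(self.transcripts.values())

    def _build_indexes(self) -> None:
        if self._indexes_built:
            return
        self.junctions: set = set()            # (chrom, start, end, strand)
        self.donors: set = set()               # (chrom, pos, strand)
        self.acceptors: set = set()
        self.gene_spans: Dict[str, Tuple[str, str, int, int]] = {}
        chains: Dict[Tuple, List[str]] = {}
        for t in self.transcripts.values():
            for (s, e) in t.introns:
                self.junctions.add((t.chrom, s, e, t.strand))
                if t.strand == "+":
                    self.donors.add((t.chrom, s, t.strand))
                    self.acceptors.add((t.chrom, e, t.strand))
                else:
                    self.donors.add((t.chrom, e, t.strand))
                    self.acceptors.add((t.chrom, s, t.strand))
            chains.setdefault((t.chrom, t.strand, t.introns), []).append(t.transcript_id)
        for gid, tids in self.genes.items():
            ts = [self.transcripts[i] for i in tids]
            chrom = ts[0].chrom
            strand = ts[0].strand
            self.gene_spans[gid] = (
                chrom,
                strand,
                min(t.start for t in ts),
                max(t.end for t in ts),
            )
        self.chains = {k: sorted(v) for k, v in chains.items()}
        # per-chromosome sorted gene span lists for overlap queries
        self._span_index: Dict[str, List[Tuple[int, int, str, str]]] = {}
        for gid, (chrom, strand, s, e) in self.gene_spans.items():
            self._span_index.setdefault(chrom, []).append((s, e, gid, strand))
        for lst in self._span_index.values():
            lst.sort()
        self._indexes_built = True

    def junction_set(self) -> set:
        self._build_indexes()
        return self.junctions

    def donor_set(self) -> set:
        self._build_indexes()
        return self.donors

    def acceptor_set(self) -> set:
        self._build_indexes()
        return self.acceptors

    def gene_span(self, gene_id: str) -> Tuple[str, str, int, int]:
        self._build_indexes()
        return self.gene_spans[gene_id]

    def transcripts_with_chain(self, chrom: str, strand: str,
                               chain: Tuple[Interval, ...]) -> List[str]:
        self._build_indexes()
        return self.chains.get((chrom, strand, chain), [])

    def genes_overlapping(self, chrom: str, start: int, end: int,
                          strand: Optional[str] = None) -> List[str]:
        """Gene ids whose span overlaps [start, end), optionally on one strand."""
        self._build_indexes()
        out = []
        for (s, e, gid, g_strand) in self._span_index.get(chrom, []):
            if s >= end:
                break
            if e > start and (strand is None or g_strand == strand):
                out.append(gid)
        return out

    def gene_transcripts(self, gene_id: str) -> List[TranscriptModel]:
        return [self.transcripts[i] for i in self.genes[gene_id]]

    def tss_positions(self) -> Dict[Tuple[str, str], np.ndarray]:
        """Sorted unique TSS positions per (chrom, strand)."""
        pos: Dict[Tuple[str, str], set] = {}
        for t in self.transcripts.values():
            pos.setdefault((t.chrom, t.strand), set()).add(t.tss)
        return {k: np.array(sorted(v), dtype=np.int64) for k, v in pos.items()}

    def pas_positions(self) -> Dict[Tuple[str, str], np.ndarray]:
        """Sorted unique PAS positions per (chrom, strand)."""
        pos: Dict[Tuple[str, str], set] = {}
        for t in self.transcripts.values():
            pos.setdefault((t.chrom, t.strand), set()).add(t.pas)
        return {k: np.array(sorted(v), dtype=np.int64) for k, v in pos.items()}


class CoverageTrack:
    """Per-chromosome step function of read depth over 0-based half-open intervals.

    Intervals are stored sorted and non-overlapping; any position not covered
    by an interval reads as depth 0.
    """

    def __init__(self):
        self._chrom: Dict[str, Tuple[np.ndarray, np.ndarray, np.ndarray]] = {}

    @classmethod
    def from_intervals(cls, intervals: Iterable[Tuple[str, int, int, float]]) -> "CoverageTrack":
        by_chrom: Dict[str, List[Tuple[int, int, float]]] = {}
        for chrom, start, end, depth in intervals:
            if depth < 0:
                raise DataError(f"negative depth {depth} at {chrom}:{start}-{end}")
            if end <= start:
                raise DataError(f"empty interval {chrom}:{start}-{end}")
            by_chrom.setdefault(chrom, []).append((int(start), int(end), float(depth)))
        track = cls()
        for chrom, ivs in by_chrom.items():
            ivs.sort()
            prev_end = -1
            for s, e, _ in ivs:
                if s < prev_end:
                    raise DataError(f"overlapping coverage intervals on {chrom} at {s}")
                prev_end = e
            starts = np.array([s for s, _, _ in ivs], dtype=np.int64)
            ends = np.array([e for _, e, _ in ivs], dtype=np.int64)
            depths = np.array([d for _, _, d in ivs], dtype=np.float64)
            track._chrom[chrom] = (starts, ends, depths)
        return track

    @classmethod
    def from_array(cls, chrom: str, depth: np.ndarray, offset: int = 0) -> "CoverageTrack":
        """Run-length encode a dense per-base depth array starting at `offset`."""
        depth = np.asarray(depth, dtype=np.float64)
        if np.any(depth < 0):
            raise DataError("negative depth in array")
        track = cls()
        if depth.size == 0:
            return track
        change = np.flatnonzero(np.diff(depth)) + 1
        starts = np.concatenate(([0], change))
        ends = np.concatenate((change, [depth.size]))
        vals = depth[starts]
        keep = vals > 0
        track._chrom[chrom] = (
            starts[keep] + offset,
            ends[keep] + offset,
            vals[keep],
        )
        return track

    def chromosomes(self) -> List[str]:
        return sorted(self._chrom)

    def intervals(self, chrom: str) -> List[Tuple[int, int, float]]:
        if chrom not in self._chrom:
            return []
        starts, ends, depths = self._chrom[chrom]
        return [(int(s), int(e), float(d)) for s, e, d in zip(starts, ends, depths)]

    def depth_at(self, chrom: str, pos: int) -> float:
        if chrom not in self._chrom:
            return 0.0
        starts, ends, depths = self._chrom[chrom]
        i = int(np.searchsorted(starts, pos, side="right")) - 1
        if i >= 0 and pos < ends[i]:
            return float(depths[i])
        return 0.0

    def integral(self, chrom: str, start: int, end: int) -> float:
        """Sum of depth x width over [start, end)."""
        if end <= start or chrom not in self._chrom:
            return 0.0
        starts, ends, depths = self._chrom[chrom]
        lo = int(np.searchsorted(ends, start, side="right"))
        hi = int(np.searchsorted(starts, end, side="left"))
        if lo >= hi:
            return 0.0
        s = np.maximum(starts[lo:hi], start)
        e = np.minimum(ends[lo:hi], end)
        w = np.maximum(e - s, 0)
        return float(np.sum(w * depths[lo:hi]))

    def mean_depth(self, chrom: str, start: int, end: int) -> float:
        if end <= start:
            raise DataError(f"empty interval [{start}, {end})")
        return self.integral(chrom, start, end) / (end - start)
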