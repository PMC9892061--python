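"""Isoform end validation against evidence pools.

Builds validated pools of 5' ends (CAGE-like peak summits plus reference
TSSs), splice junctions (short-read junction counts), and 3' ends
(PolyA-Seq / 3'-end-seq positions with at least `min_pas_reads` supporting
reads, plus reference PASs); scores each isoform's TSS/junction/PAS support
within a fixed window; deduplicates isoforms that share a splicing structure
and PAS; and assigns full-length (FLNC) reads to isoforms per condition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .io import BedRecord
from .models import Annotation, DataError, Interval, TranscriptModel


@dataclass
class EvidencePools:
    """Validated 5'-end, junction, and 3'-end evidence.

    Positions are sorted, deduplicated numpy arrays per (chrom, strand);
    junction counts are summed read counts per exact intron coordinate.
    """

    tss: Dict[Tuple[str, str], np.ndarray]
    pas: Dict[Tuple[str, str], np.ndarray]
    junctions: Dict[Tuple[str, int, int, str], int]
    sources: Tuple[str, ...] = ()

    def nearest_tss_distance(self, chrom: str, strand: str, pos: int) -> float:
        return _nearest(self.tss.get((chrom, strand)), pos)

    def nearest_pas_distance(self, chrom: str, strand: str, pos: int) -> float:
        return _nearest(self.pas.get((chrom, strand)), pos)


def _nearest(arr: Optional[np.ndarray], pos: int) -> float:
    if arr is None or arr.size == 0:
        return math.inf
    i = int(np.searchsorted(arr, pos))
    best = math.inf
    if i < arr.size:
        best = min(best, abs(int(arr[i]) - pos))
    if i > 0:
        best = min(best, abs(int(arr[i - 1]) - pos))
    return float(best)


def _stranded_positions(records: Iterable[Tuple[str, str, int]]) -> Dict[Tuple[str, str], np.ndarray]:
    pos: Dict[Tuple[str, str], set] = {}
    for chrom, strand, p in records:
        pos.setdefault((chrom, strand), set()).add(int(p))
    return {k: np.array(sorted(v), dtype=np.int64) for k, v in pos.items()}


def build_evidence_pools(
    cage: Sequence[BedRecord],
    pas_reads: Sequence[BedRecord],
    junction_tables: Sequence[pd.DataFrame],
    reference: Annotation,
    min_pas_reads: int = 5,
) -> EvidencePools:
    """Union evidence sources into validated pools.

    CAGE peaks contribute their interval midpoint (summit proxy); 3'-end
    evidence positions contribute when their read count (BED score) is at
    least `min_pas_reads`; reference TSSs and PASs are always included.
    Unstranded BED records contribute to both strands.
    """
    if len(reference) == 0:
        raise DataError("empty reference annotation")

    def expand(rec: BedRecord, pos: int):
        strands = (rec.strand,) if rec.strand in ("+", "-") else ("+", "-")
        for s in strands:
            yield (rec.chrom, s, pos)

    tss_records: List[Tuple[str, str, int]] = []
    for rec in cage:
        tss_records.extend(expand(rec, rec.midpoint))
    for (chrom, strand), arr in reference.tss_positions().items():
        tss_records.extend((chrom, strand, int(p)) for p in arr)

    pas_records: List[Tuple[str, str, int]] = []
    for rec in pas_reads:
        if rec.score >= min_pas_reads:
            pas_records.extend(expand(rec, rec.start))
    for (chrom, strand), arr in reference.pas_positions().items():
        pas_records.extend((chrom, strand, int(p)) for p in arr)

    junctions: Dict[Tuple[str, int, int, str], int] = {}
    for table in junction_tables:
        for row in table.itertuples(index=False):
            key = (row.chrom, int(row.start), int(row.end), row.strand)
            junctions[key] = junctions.get(key, 0) + int(row.count)

    return EvidencePools(
        tss=_stranded_positions(tss_records),
        pas=_stranded_positions(pas_records),
        junctions=junctions,
    )


@dataclass
class SupportReport:
    transcript_id: str
    tss_supported: bool
    tss_distance: float
    pas_supported: bool
    pas_distance: float
    junctions: List[Tuple[Interval, bool, int]]  # (intron, supported, pool count)
    fully_supported: bool


def evaluate_support(
    isoform: TranscriptModel,
    pools: EvidencePools,
    end_window: int = 50,
    min_junction_reads: int = 2,
) -> SupportReport:
    """Score one isoform's TSS, PAS and junction support against the pools.

    End windows are inclusive (distance <= end_window counts as supported);
    junction support requires an exact intron coordinate match with at least
    `min_junction_reads` pooled reads.
    """
    tss_d = pools.nearest_tss_distance(isoform.chrom, isoform.strand, isoform.tss)
    pas_d = pools.nearest_pas_distance(isoform.chrom, isoform.strand, isoform.pas)
    tss_ok = tss_d <= end_window
    pas_ok = pas_d <= end_window
    junctions = []
    all_junctions_ok = True
    for intron in isoform.introns:
        count = pools.junctions.get(
            (isoform.chrom, intron[0], intron[1], isoform.strand), 0
        )
        ok = count >= min_junction_reads
        all_junctions_ok = all_junctions_ok and ok
        junctions.append((intron, ok, count))
    return SupportReport(
        transcript_id=isoform.transcript_id,
        tss_supported=tss_ok,
        tss_distance=tss_d,
        pas_supported=pas_ok,
        pas_distance=pas_d,
        junctions=junctions,
        fully_supported=tss_ok and pas_ok and all_junctions_ok,
    )


def _tss_pool_distance(iso: TranscriptModel, pools: EvidencePools) -> float:
    return pools.nearest_tss_distance(iso.chrom, iso.strand, iso.tss)


def _five_prime_key(iso: TranscriptModel) -> int:
    # smaller is more 5' on '+', larger is more 5' on '-'
    return iso.tss if iso.strand == "+" else -iso.tss


def deduplicate_by_tss(
    isoforms: Sequence[TranscriptModel],
    pools: EvidencePools,
    pas_window: int = 50,
) -> Tuple[List[TranscriptModel], Dict[str, str]]:
    """Collapse isoforms that share a junction chain and PAS (within window).

    Within each group the isoform whose TSS is closest to the 5'-end pool is
    kept (ties keep the 5'-most TSS, then lexicographically smallest id).
    Mono-exon isoforms are grouped only when both ends are mutually within
    the window.  Returns the kept isoforms (input order) and a map from each
    dropped id to its keeper.
    """
    groups: List[List[TranscriptModel]] = []
    multi_bins: Dict[Tuple, List[TranscriptModel]] = {}
    mono_bins: Dict[Tuple, List[TranscriptModel]] = {}
    for iso in isoforms:
        if iso.is_multi_exon:
            multi_bins.setdefault((iso.chrom, iso.strand, iso.introns), []).append(iso)
        else:
            mono_bins.setdefault((iso.chrom, iso.strand), []).append(iso)

    def linkage_groups(members: List[TranscriptModel], linked) -> None:
        # single-linkage connected components under the `linked` predicate
        remaining = list(members)
        while remaining:
            comp = [remaining.pop(0)]
            changed = True
            while changed:
                changed = False
                for other in list(remaining):
                    if any(linked(other, m) for m in comp):
                        comp.append(other)
                        remaining.remove(other)
                        changed = True
            groups.append(comp)

    for members in multi_bins.values():
        linkage_groups(members, lambda a, b: abs(a.pas - b.pas) <= pas_window)
    for members in mono_bins.values():
        linkage_groups(
            members,
            lambda a, b: abs(a.pas - b.pas) <= pas_window
            and abs(a.tss - b.tss) <= pas_window,
        )

    kept_ids = set()
    dropped_to_kept: Dict[str, str] = {}
    for comp in groups:
        keeper = min(
            comp,
            key=lambda m: (
                _tss_pool_distance(m, pools),
                _five_prime_key(m),
                m.transcript_id,
            ),
        )
        kept_ids.add(keeper.transcript_id)
        for m in comp:
            if m.transcript_id != keeper.transcript_id:
                dropped_to_kept[m.transcript_id] = keeper.transcript_id
    kept = [iso for iso in isoforms if iso.transcript_id in kept_ids]
    return kept, dropped_to_kept


@dataclass
class FlncAssignment:
    """FLNC read counts per (transcript, condition) plus unassigned tallies."""

    counts: Dict[Tuple[str, str], int] = field(default_factory=dict)
    unassigned: Dict[str, int] = field(default_factory=dict)
    totals: Dict[str, int] = field(default_factory=dict)

    def count(self, transcript_id: str, condition: str) -> int:
        return self.counts.get((transcript_id, condition), 0)

    def add(self, transcript_id: Optional[str], condition: str, n: int = 1) -> None:
        self.totals[condition] = self.totals.get(condition, 0) + n
        if transcript_id is None:
            self.unassigned[condition] = self.unassigned.get(condition, 0) + n
        else:
            key = (transcript_id, condition)
            self.counts[key] = self.counts.get(key, 0) + n

    @classmethod
    def from_count_table(cls, table: pd.DataFrame) -> "FlncAssignment":
        """Build from a TSV-derived table (transcript_id, gene_id, sample, count)."""
        out = cls()
        for row in table.itertuples(index=False):
            out.add(row.transcript_id, row.sample, int(row.count))
        return out


def assign_flnc_reads(
    flnc_models: Mapping[str, Sequence[TranscriptModel]],
    isoforms: Annotation,
    end_window: int = 50,
) -> FlncAssignment:
    """Assign FLNC reads (as aligned exon chains) to catalog isoforms.

    A multi-exon read supports an isoform iff their junction chains are
    identical and both ends lie within `end_window`; a mono-exon read can
    only support a mono-exon isoform, with both ends mutually within the
    window.  A read matching several isoforms goes to the smallest summed
    end distance; residual ties are left unassigned.
    """
    mono_by_loc: Dict[Tuple[str, str], List[TranscriptModel]] = {}
    for t in isoforms:
        if not t.is_multi_exon:
            mono_by_loc.setdefault((t.chrom, t.strand), []).append(t)

    assignment = FlncAssignment()
    for condition, reads in flnc_models.items():
        for read in reads:
            candidates: List[TranscriptModel] = []
            if read.is_multi_exon:
                for tid in isoforms.transcripts_with_chain(
                    read.chrom, read.strand, read.introns
                ):
                    candidates.append(isoforms.transcripts[tid])
            else:
                candidates = [
                    t
                    for t in mono_by_loc.get((read.chrom, read.strand), [])
                ]
            scored = []
            for t in candidates:
                d5 = abs(read.tss - t.tss)
                d3 = abs(read.pas - t.pas)
                if d5 <= end_window and d3 <= end_window:
                    scored.append((d5 + d3, t.transcript_id))
            if not scored:
                assignment.add(None, condition)
                continue
            scored.sort()
            if len(scored) > 1 and scored[0][0] == scored[1][0]:
                assignment.add(None, condition)  # unresolvable tie
            else:
                assignment.add(scored[0][1], condition)
    return assignment


def summarize_support(reports: Sequence[SupportReport]) -> Dict[str, float]:
    """Percent of isoforms with supported TSS / PAS, and of junctions supported."""
    if not reports:
        raise DataError("no support reports to summarize")
    n = len(reports)
    tss = sum(r.tss_supported for r in reports)
    pas = sum(r.pas_supported for r in reports)
    n_junc = sum(len(r.junctions) for r in reports)
    juncs_ok = sum(ok for r in reports for (_, ok, _) in r.junctions)
    return {
        "tss_rate": 100.0 * tss / n,
        "pas_rate": 100.0 * pas / n,
        "junction_rate": (100.0 * juncs_ok / n_junc) if n_junc else 100.0,
        "n_isoforms": float(n),
        "n_junctions": float(n_junc),
    }
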