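"""Alternative polyadenylation: PAS clustering, sequence context, PDUI.

PAS positions are clustered by single-linkage chaining at a 50-bp window;
a cluster is known when its representative lies within 50 nt of a
reference PAS.  For genes with at least two PAS on their longest terminal
exon, a two-PAS model splits the exon into a common region (upstream of
the proximal PAS, covered by all isoforms) and an extended region (between
proximal and distal PAS, covered only by distal isoforms).  The distal PAS
usage index (PDUI) is the ratio of mean short-read coverage in the
extended region to that in the common region, which equals the distal
isoform fraction under uniform within-transcript coverage.  Differential
APA between two conditions is a Fisher exact test on coverage-derived read
proxies, gated on |delta PDUI|.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .models import (
    Annotation,
    CoverageTrack,
    DataError,
    GenomeSequence,
    Interval,
    reverse_complement,
)
from .stats import bh_adjust, fisher_exact_2x2


@dataclass
class PasCluster:
    cluster_id: str
    chrom: str
    strand: str
    representative: int
    members: Tuple[int, ...]
    support: int
    known: Optional[bool] = None


@dataclass
class ApaRegion:
    gene_id: str
    chrom: str
    strand: str
    common: Interval     # terminal-exon start (strand-aware) to proximal PAS
    extended: Interval   # proximal to distal PAS
    proximal: int
    distal: int


@dataclass
class PduiRecord:
    gene_id: str
    pdui_ctrl: float
    pdui_treat: float
    delta_pdui: float
    p_value: float = math.nan
    adjusted_p: float = math.nan
    call: str = "unchanged"  # shortened / lengthened / unchanged


def cluster_pas_sites(
    positions: Mapping[Tuple[str, str], Sequence[Tuple[int, int]]],
    window: int = 50,
) -> List[PasCluster]:
    """Single-linkage clustering of (position, support) pairs per (chrom, strand).

    Consecutive sorted positions at most `window` apart chain into one
    cluster; the representative is the maximum-support member (ties go to
    the strand-5'-most member); support is the member sum.
    """
    clusters: List[PasCluster] = []
    for (chrom, strand) in sorted(positions):
        entries = sorted(positions[(chrom, strand)])
        if not entries:
            continue
        runs: List[List[Tuple[int, int]]] = [[entries[0]]]
        for pos, support in entries[1:]:
            if pos - runs[-1][-1][0] <= window:
                runs[-1].append((pos, support))
            else:
                runs.append([(pos, support)])
        for i, run in enumerate(runs, start=1):
            five_prime_sign = 1 if strand == "+" else -1
            rep = max(run, key=lambda e: (e[1], five_prime_sign * -e[0]))[0]
            clusters.append(
                PasCluster(
                    cluster_id=f"pas:{chrom}:{strand}:{i}",
                    chrom=chrom,
                    strand=strand,
                    representative=rep,
                    members=tuple(p for p, _ in run),
                    support=sum(s for _, s in run),
                )
            )
    return clusters


def label_pas_clusters(
    clusters: Sequence[PasCluster],
    reference: Annotation,
    window: int = 50,
) -> List[PasCluster]:
    """Set the known flag: representative within `window` of a same-strand reference PAS."""
    ref_pas = reference.pas_positions()
    for c in clusters:
        arr = ref_pas.get((c.chrom, c.strand))
        if arr is None or arr.size == 0:
            c.known = False
            continue
        i = int(np.searchsorted(arr, c.representative))
        d = math.inf
        if i < arr.size:
            d = min(d, abs(int(arr[i]) - c.representative))
        if i > 0:
            d = min(d, abs(int(arr[i - 1]) - c.representative))
        c.known = d <= window
    return list(clusters)


def _context_window(genome: GenomeSequence, chrom: str, strand: str,
                    pos: int, flank: int) -> Optional[str]:
    """Transcript-oriented sequence covering offsets [-flank, +flank) around a PAS.

    Offset -1 is the last transcribed base, offset 0 the first downstream
    base.  Returns None when the window crosses a chromosome edge.
    """
    n = genome.lengths[chrom]
    if pos - flank < 0 or pos + flank > n:
        return None
    seq = genome.fetch(chrom, pos - flank, pos + flank)
    return seq if strand == "+" else reverse_complement(seq)


def pas_nucleotide_profile(
    clusters: Sequence[PasCluster],
    genome: GenomeSequence,
    flank: int = 25,
) -> pd.DataFrame:
    """Base frequency per offset in [-flank, +flank) around cluster representatives.

    Strand-corrected (reverse-complemented on '-'); clusters whose window
    crosses a chromosome edge are skipped.  Returns a DataFrame indexed by
    offset with columns A/C/G/T plus an n_clusters attribute row-free count.
    """
    if not clusters:
        raise DataError("no PAS clusters to profile")
    width = 2 * flank
    counts = {b: np.zeros(width, dtype=np.int64) for b in "ACGT"}
    used = 0
    for c in clusters:
        seq = _context_window(genome, c.chrom, c.strand, c.representative, flank)
        if seq is None:
            continue
        used += 1
        for i, base in enumerate(seq):
            if base in counts:
                counts[base][i] += 1
    if used == 0:
        raise DataError("all clusters fell on chromosome edges")
    df = pd.DataFrame(
        {b: counts[b] / used for b in "ACGT"},
        index=pd.Index(range(-flank, flank), name="offset"),
    )
    df.attrs["n_clusters"] = used
    df.attrs["n_skipped"] = len(clusters) - used
    return df


def scan_polya_signal(
    clusters: Sequence[PasCluster],
    genome: GenomeSequence,
    upstream_window: int = 50,
    motif: str = "AATAAA",
) -> float:
    """Fraction of clusters whose strand-corrected upstream window contains the motif."""
    if not clusters:
        raise DataError("no PAS clusters to scan")
    hits = 0
    total = 0
    for c in clusters:
        p = c.representative
        if c.strand == "+":
            seq = genome.fetch_clamped(c.chrom, p - upstream_window, p)
        else:
            seq = reverse_complement(genome.fetch_clamped(c.chrom, p, p + upstream_window))
        total += 1
        if motif in seq:
            hits += 1
    return hits / total


def build_apa_regions(
    isoforms: Annotation,
    clusters: Sequence[PasCluster],
    min_extended: int = 50,
) -> List[ApaRegion]:
    """Two-PAS regions per gene from cluster representatives on the longest terminal exon.

    Proximal is the strand-5'-most candidate, distal the strand-3'-most;
    intermediate PASs are ignored.  Genes with fewer than two candidates or
    an extended region shorter than `min_extended` yield no region.
    """
    reps: Dict[Tuple[str, str], List[int]] = {}
    for c in clusters:
        reps.setdefault((c.chrom, c.strand), []).append(c.representative)
    regions = []
    for gene_id in sorted(isoforms.genes):
        transcripts = isoforms.gene_transcripts(gene_id)
        chrom, strand = transcripts[0].chrom, transcripts[0].strand
        term = max(
            (t.terminal_exon for t in transcripts), key=lambda iv: iv[1] - iv[0]
        )
        candidates = [
            r
            for r in reps.get((chrom, strand), [])
            if term[0] <= r <= term[1]
        ]
        if len(candidates) < 2:
            continue
        if strand == "+":
            proximal, distal = min(candidates), max(candidates)
            common = (term[0], proximal)
            extended = (proximal, distal)
        else:
            proximal, distal = max(candidates), min(candidates)
            common = (proximal, term[1])
            extended = (distal, proximal)
        if extended[1] - extended[0] < min_extended or common[1] - common[0] < 1:
            continue
        regions.append(
            ApaRegion(
                gene_id=gene_id,
                chrom=chrom,
                strand=strand,
                common=common,
                extended=extended,
                proximal=proximal,
                distal=distal,
            )
        )
    return regions


def quantify_pdui(region: ApaRegion, coverage: CoverageTrack) -> float:
    """Distal PAS usage index: mean extended-region depth over mean common-region depth.

    Equals the distal-isoform fraction under uniform within-transcript
    coverage.  Returns NaN when the common region has zero coverage.
    """
    common_mean = coverage.mean_depth(region.chrom, *region.common)
    if common_mean == 0:
        return math.nan
    extended_mean = coverage.mean_depth(region.chrom, *region.extended)
    return min(1.0, max(0.0, extended_mean / common_mean))


def test_differential_apa(
    regions: Sequence[ApaRegion],
    coverage_ctrl: CoverageTrack,
    coverage_treat: CoverageTrack,
    fdr_threshold: float = 0.05,
    min_delta: float = 0.2,
    read_length: int = 150,
) -> List[PduiRecord]:
    """Fisher exact test of (condition x region) coverage-derived read proxies.

    Read proxies are round(mean depth x region length / read_length) per
    region and condition.  A gene is called shortened (lengthened) when
    delta PDUI <= -min_delta (>= +min_delta) with BH-adjusted p below
    `fdr_threshold`.  Regions with undefined PDUI in either condition are
    excluded.
    """
    records: List[PduiRecord] = []
    testable: List[PduiRecord] = []
    for region in regions:
        pdui_c = quantify_pdui(region, coverage_ctrl)
        pdui_t = quantify_pdui(region, coverage_treat)
        rec = PduiRecord(
            gene_id=region.gene_id,
            pdui_ctrl=pdui_c,
            pdui_treat=pdui_t,
            delta_pdui=pdui_t - pdui_c,
        )
        records.append(rec)
        if math.isnan(pdui_c) or math.isnan(pdui_t):
            continue
        def proxy(cov: CoverageTrack, iv: Interval) -> int:
            return round(cov.mean_depth(region.chrom, *iv) * (iv[1] - iv[0]) / read_length)
        table = [
            [proxy(coverage_ctrl, region.common), proxy(coverage_ctrl, region.extended)],
            [proxy(coverage_treat, region.common), proxy(coverage_treat, region.extended)],
        ]
        if sum(table[0]) == 0 or sum(table[1]) == 0:
            continue
        rec.p_value = fisher_exact_2x2(table)
        testable.append(rec)
    if testable:
        adjusted = bh_adjust([r.p_value for r in testable])
        for rec, padj in zip(testable, adjusted):
            rec.adjusted_p = padj
            if padj < fdr_threshold and rec.delta_pdui <= -min_delta:
                rec.call = "shortened"
            elif padj < fdr_threshold and rec.delta_pdui >= min_delta:
                rec.call = "lengthened"
    return records
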