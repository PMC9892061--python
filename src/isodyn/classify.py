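"""Structural classification of isoforms against a reference annotation.

Each isoform gets exactly one of eight categories by a decision cascade:
full splice match (FSM), incomplete splice match (ISM), novel in catalog
(NIC), novel not in catalog (NNC), fusion, antisense, genic, intergenic.
Also flags likely internal-priming artifacts: isoforms whose genomic
context immediately downstream of the PAS is A-rich, the signature of
oligo(dT) mispriming on genomic adenine tracts rather than a poly(A) tail.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

from .models import (
    Annotation,
    DataError,
    GenomeSequence,
    TranscriptModel,
    reverse_complement,
)

CATEGORIES = (
    "FSM",
    "ISM",
    "NIC",
    "NNC",
    "genic",
    "fusion",
    "antisense",
    "intergenic",
)


@dataclass
class StructuralCall:
    transcript_id: str
    category: str
    matched_reference_id: Optional[str] = None
    internal_priming: bool = False


def _is_consecutive_subchain(chain, ref_chain) -> bool:
    n, m = len(chain), len(ref_chain)
    if n == 0 or n >= m:
        return False
    for i in range(m - n + 1):
        if tuple(ref_chain[i:i + n]) == tuple(chain):
            return True
    return False


def classify_isoform(
    isoform: TranscriptModel,
    reference: Annotation,
    mono_end_window: int = 50,
) -> StructuralCall:
    """Classify one isoform against the reference via the category cascade."""
    chrom, strand = isoform.chrom, isoform.strand
    same = reference.genes_overlapping(chrom, isoform.start, isoform.end, strand)
    anti = reference.genes_overlapping(
        chrom, isoform.start, isoform.end, "-" if strand == "+" else "+"
    )

    if not isoform.is_multi_exon:
        # mono-exon: exact-span match (both ends within window) against a
        # mono-exon reference transcript, else positional categories only.
        best = None
        for gid in same:
            for t in reference.gene_transcripts(gid):
                if t.is_multi_exon:
                    continue
                if (
                    abs(t.start - isoform.start) <= mono_end_window
                    and abs(t.end - isoform.end) <= mono_end_window
                ):
                    if best is None or t.transcript_id < best:
                        best = t.transcript_id
        if best is not None:
            return StructuralCall(isoform.transcript_id, "FSM", best)
        if same:
            return StructuralCall(isoform.transcript_id, "genic")
        if anti:
            return StructuralCall(isoform.transcript_id, "antisense")
        return StructuralCall(isoform.transcript_id, "intergenic")

    chain = isoform.introns
    # FSM / ISM: chain equality, then consecutive sub-chain containment
    fsm_ids = reference.transcripts_with_chain(chrom, strand, chain)
    if fsm_ids:
        return StructuralCall(isoform.transcript_id, "FSM", fsm_ids[0])
    ism_match = None
    candidate_genes = same if same else list(reference.genes)
    seen = set()
    for gid in candidate_genes:
        if gid in seen:
            continue
        seen.add(gid)
        g_chrom, g_strand, _, _ = reference.gene_span(gid)
        if g_chrom != chrom or g_strand != strand:
            continue
        for t in reference.gene_transcripts(gid):
            if _is_consecutive_subchain(chain, t.introns):
                if ism_match is None or t.transcript_id < ism_match:
                    ism_match = t.transcript_id
    if ism_match is not None:
        return StructuralCall(isoform.transcript_id, "ISM", ism_match)

    # fusion: spanning >= 2 same-strand genes whose own spans do not overlap
    if len(same) >= 2:
        spans = [reference.gene_span(g) for g in same]
        for i in range(len(spans)):
            for j in range(i + 1, len(spans)):
                (_, _, s1, e1), (_, _, s2, e2) = spans[i], spans[j]
                if e1 <= s2 or e2 <= s1:
                    return StructuralCall(isoform.transcript_id, "fusion")

    donors = reference.donor_set()
    acceptors = reference.acceptor_set()
    all_annotated = True
    for (s, e) in chain:
        d = (chrom, s, strand) if strand == "+" else (chrom, e, strand)
        a = (chrom, e, strand) if strand == "+" else (chrom, s, strand)
        if d not in donors or a not in acceptors:
            all_annotated = False
            break
    if same and all_annotated:
        return StructuralCall(isoform.transcript_id, "NIC")
    if same:
        return StructuralCall(isoform.transcript_id, "NNC")
    if anti:
        return StructuralCall(isoform.transcript_id, "antisense")
    return StructuralCall(isoform.transcript_id, "intergenic")


def detect_internal_priming(
    isoform: TranscriptModel,
    genome: GenomeSequence,
    window: int = 20,
    a_run: int = 6,
    a_fraction: float = 0.60,
) -> bool:
    """True iff the window downstream of the PAS is genomically A-rich.

    The window is read in transcript orientation ('A' on '+', complemented
    'T' on '-'); the flag fires on `a_run` consecutive adenines or on an
    adenine fraction strictly greater than `a_fraction`.  Windows truncated
    at a chromosome edge are evaluated over the available bases.
    """
    if window <= 0:
        return False
    p = isoform.pas
    if isoform.strand == "+":
        seq = genome.fetch_clamped(isoform.chrom, p, p + window)
    else:
        seq = reverse_complement(genome.fetch_clamped(isoform.chrom, p - window, p))
    if not seq:
        return False
    if "A" * a_run in seq:
        return True
    return seq.count("A") / len(seq) > a_fraction


def classify_catalog(
    isoforms: Annotation,
    reference: Annotation,
    genome: Optional[GenomeSequence] = None,
) -> List[StructuralCall]:
    calls = []
    for t in sorted(isoforms, key=lambda t: t.transcript_id):
        call = classify_isoform(t, reference)
        if genome is not None:
            call.internal_priming = detect_internal_priming(t, genome)
        calls.append(call)
    return calls


def summarize_structural_categories(
    calls: Sequence[StructuralCall],
    categories: Optional[Sequence[str]] = None,
) -> Dict[str, Dict[str, float]]:
    """Per-category counts and percentages (2-decimal), over all provided calls.

    `categories` optionally restricts both the tallied calls and the
    denominator (e.g. to the known-gene categories), mirroring summaries
    computed on a filtered slice of a catalog.
    """
    if not calls:
        raise DataError("no structural calls to summarize")
    if categories is not None:
        calls = [c for c in calls if c.category in set(categories)]
        if not calls:
            raise DataError("no calls left after category filter")
    total = len(calls)
    out: Dict[str, Dict[str, float]] = {}
    for cat in CATEGORIES:
        n = sum(1 for c in calls if c.category == cat)
        out[cat] = {"count": n, "percent": round(100.0 * n / total, 2)}
    out["total"] = {"count": total, "percent": 100.0}
    return out
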