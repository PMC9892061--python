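"""Local alternative-splicing events, PSI quantification, differential calling.

Events are enumerated by pairwise comparison of transcript exon chains
within each gene and deduplicated by (type, defining coordinates):

* SE  - exon skipping: an internal exon with both flanking introns in one
        chain vs the direct flank-to-flank intron in the other.
* A5 / A3 - two introns sharing one boundary and differing at the donor
        (A5) or acceptor (A3) side, strand-aware.
* MX  - two mutually exclusive internal exons between shared flanks.
* IR  - one chain's exon spans the other's intron with both outer
        boundaries shared (intron retention).
* AF / AL - distinct, non-overlapping first (last) exons whose first (last)
        introns share the inner boundary.

PSI is the inclusion-form fraction of TPM; the differential test is a
Fisher exact test on pseudo-counts obtained by splitting `count_scale`
proportionally to the pooled inclusion/exclusion TPM of each condition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .models import Annotation, DataError, TranscriptModel
from .stats import bh_adjust, fisher_exact_2x2

EVENT_TYPES = ("SE", "A5", "A3", "MX", "IR", "AF", "AL")


@dataclass
class ASEvent:
    event_id: str
    gene_id: str
    etype: str
    coords: Tuple
    inclusion: FrozenSet[str]
    exclusion: FrozenSet[str]
    novel: bool = False

    def __post_init__(self):
        if not self.inclusion or not self.exclusion:
            raise DataError(f"{self.event_id}: empty inclusion or exclusion set")
        if self.inclusion & self.exclusion:
            raise DataError(f"{self.event_id}: overlapping inclusion/exclusion sets")


@dataclass
class PsiRecord:
    event_id: str
    gene_id: str
    etype: str
    novel: bool
    psi: Dict[str, float]            # sample -> PSI (nan when undefined)
    pooled_inclusion: Dict[str, float]  # condition -> pooled inclusion TPM
    pooled_exclusion: Dict[str, float]
    mean_psi: Dict[str, float]       # condition -> mean over defined samples
    delta_psi: float = math.nan
    p_value: float = math.nan
    adjusted_p: float = math.nan
    significant: Optional[bool] = None


def _overlap(a: Tuple[int, int], b: Tuple[int, int]) -> bool:
    return a[0] < b[1] and b[0] < a[1]


def _pair_events(t1: TranscriptModel, t2: TranscriptModel) -> List[Tuple[str, Tuple, str, str]]:
    """Raw events from one ordered transcript pair: (etype, coords, inc_id, exc_id)."""
    out = []
    strand = t1.strand
    introns1, introns2 = t1.introns, t2.introns
    set2 = set(introns2)
    exons1, exons2 = t1.exons, t2.exons

    # SE: internal exon of t1 skipped in t2
    for k in range(1, len(exons1) - 1):
        left = (exons1[k - 1][1], exons1[k][0])
        right = (exons1[k][1], exons1[k + 1][0])
        if (left[0], right[1]) in set2:
            coords = (left, right)
            out.append(("SE", coords, t1.transcript_id, t2.transcript_id))

    # IR: t1 exon spans a t2 intron with shared outer boundaries
    exon_set1 = set(exons1)
    for j, intron in enumerate(introns2):
        # flanking exons of this intron in t2 (genomic order)
        left_exon = exons2[j]
        right_exon = exons2[j + 1]
        if (left_exon[0], right_exon[1]) in exon_set1:
            coords = (left_exon[0], intron[0], intron[1], right_exon[1])
            out.append(("IR", coords, t1.transcript_id, t2.transcript_id))

    # MX: mutually exclusive internal exons between shared outer flank coords
    for k in range(1, len(exons1) - 1):
        e1 = exons1[k]
        c1 = exons1[k - 1][1]
        c2 = exons1[k + 1][0]
        for m in range(1, len(exons2) - 1):
            e2 = exons2[m]
            if _overlap(e1, e2):
                continue
            if exons2[m - 1][1] == c1 and exons2[m + 1][0] == c2:
                lo, hi = sorted([e1, e2])
                coords = (c1, lo, hi, c2)
                # inclusion carries the 5'-proximal exon along the transcript
                if (strand == "+" and e1 < e2) or (strand == "-" and e1 > e2):
                    out.append(("MX", coords, t1.transcript_id, t2.transcript_id))
                else:
                    out.append(("MX", coords, t2.transcript_id, t1.transcript_id))

    # intron pairs sharing exactly one boundary: A5 / A3 / AF / AL.
    # A genuine A5/A3 needs the exons flanking the differing boundary to
    # overlap (the alternative site lies within one exon body); first/last
    # exons that do NOT overlap give AF/AL instead.  Pairs satisfying
    # neither (e.g. an exon-skip flank against the skip junction) are not
    # donor/acceptor events at all.
    fi1, fi2 = t1.first_intron, t2.first_intron
    li1, li2 = t1.last_intron, t2.last_intron
    for j1, i1 in enumerate(introns1):
        for j2, i2 in enumerate(introns2):
            if i1 == i2:
                continue
            shared_end = i1[1] == i2[1] and i1[0] != i2[0]
            shared_start = i1[0] == i2[0] and i1[1] != i2[1]
            if not (shared_end or shared_start):
                continue
            lo, hi = sorted([i1, i2])
            # exons adjacent to the differing (non-shared) boundary
            if shared_end:
                adj1, adj2 = exons1[j1], exons2[j2]              # left exons
            else:
                adj1, adj2 = exons1[j1 + 1], exons2[j2 + 1]      # right exons
            # donor side is the genomic-left boundary on '+', right on '-'
            differ_at_donor = shared_end if strand == "+" else shared_start
            both_first = i1 == fi1 and i2 == fi2
            both_last = i1 == li1 and i2 == li2
            if differ_at_donor and both_first and not _overlap(t1.first_exon, t2.first_exon):
                lo_e, hi_e = sorted([t1.first_exon, t2.first_exon])
                coords = (lo_e, hi_e, lo, hi)
                # inclusion: the transcript whose first exon is 5'-distal
                # (genomically left on '+'): it retains the longer 5' path
                if (strand == "+" and t1.first_exon < t2.first_exon) or (
                    strand == "-" and t1.first_exon > t2.first_exon
                ):
                    out.append(("AF", coords, t1.transcript_id, t2.transcript_id))
                else:
                    out.append(("AF", coords, t2.transcript_id, t1.transcript_id))
            elif (not differ_at_donor) and both_last and not _overlap(t1.terminal_exon, t2.terminal_exon):
                lo_e, hi_e = sorted([t1.terminal_exon, t2.terminal_exon])
                coords = (lo_e, hi_e, lo, hi)
                if (strand == "+" and t1.terminal_exon < t2.terminal_exon) or (
                    strand == "-" and t1.terminal_exon > t2.terminal_exon
                ):
                    out.append(("AL", coords, t1.transcript_id, t2.transcript_id))
                else:
                    out.append(("AL", coords, t2.transcript_id, t1.transcript_id))
            elif _overlap(adj1, adj2):
                etype = "A5" if differ_at_donor else "A3"
                coords = (lo, hi)
                # inclusion: the shorter intron (the extended exon form)
                len1 = i1[1] - i1[0]
                len2 = i2[1] - i2[0]
                if len1 < len2:
                    out.append((etype, coords, t1.transcript_id, t2.transcript_id))
                elif len2 < len1:
                    out.append((etype, coords, t2.transcript_id, t1.transcript_id))
    return out


def _enumerate_raw(annotation: Annotation) -> Dict[Tuple[str, str, Tuple], Tuple[Set[str], Set[str]]]:
    """(gene, etype, coords) -> (inclusion ids, exclusion ids), merged over pairs."""
    events: Dict[Tuple[str, str, Tuple], Tuple[Set[str], Set[str]]] = {}
    for gene_id in sorted(annotation.genes):
        transcripts = annotation.gene_transcripts(gene_id)
        for i in range(len(transcripts)):
            for j in range(i + 1, len(transcripts)):
                t1, t2 = transcripts[i], transcripts[j]
                raw = _pair_events(t1, t2) + _pair_events(t2, t1)
                for (etype, coords, inc, exc) in raw:
                    key = (gene_id, etype, coords)
                    inc_set, exc_set = events.setdefault(key, (set(), set()))
                    inc_set.add(inc)
                    exc_set.add(exc)
    # a transcript supporting the inclusion structure cannot also support
    # exclusion for the same coordinates; assert instead of silently fixing
    for key, (inc, exc) in events.items():
        both = inc & exc
        if both:
            raise DataError(f"transcript(s) {sorted(both)} on both sides of event {key}")
    return events


def _coord_string(coords) -> str:
    parts = []
    for c in coords:
        if isinstance(c, tuple):
            parts.append("-".join(str(x) for x in c))
        else:
            parts.append(str(c))
    return ":".join(parts)


def enumerate_events(
    isoforms: Annotation, reference: Optional[Annotation] = None
) -> List[ASEvent]:
    """All local AS events in the catalog; novel iff absent from the
    event set generated from the reference alone."""
    raw = _enumerate_raw(isoforms)
    ref_keys: Set[Tuple[str, Tuple]] = set()
    if reference is not None:
        ref_keys = {(etype, coords) for (_, etype, coords) in _enumerate_raw(reference)}
    events = []
    for (gene_id, etype, coords) in sorted(raw, key=lambda k: (k[0], k[1], _coord_string(k[2]))):
        inc, exc = raw[(gene_id, etype, coords)]
        chrom = next(iter(isoforms.gene_transcripts(gene_id))).chrom
        strand = next(iter(isoforms.gene_transcripts(gene_id))).strand
        event_id = f"{gene_id};{etype}:{chrom}:{_coord_string(coords)}:{strand}"
        events.append(
            ASEvent(
                event_id=event_id,
                gene_id=gene_id,
                etype=etype,
                coords=coords,
                inclusion=frozenset(inc),
                exclusion=frozenset(exc),
                novel=reference is not None and (etype, coords) not in ref_keys,
            )
        )
    return events


def compute_psi(
    events: Sequence[ASEvent],
    tpm: pd.DataFrame,
    sample_conditions: Mapping[str, str],
    conditions: Tuple[str, str],
) -> List[PsiRecord]:
    """PSI per sample and pooled per-condition TPM sums for each event.

    Transcripts missing from the TPM table contribute 0.  PSI is NA in a
    sample where inclusion + exclusion TPM is 0; the condition mean is over
    defined samples; delta is mean(treat) - mean(ctrl).
    """
    cond_ctrl, cond_treat = conditions
    samples = [s for s in tpm.columns]
    records = []
    for ev in events:
        inc_ids = [t for t in sorted(ev.inclusion) if t in tpm.index]
        exc_ids = [t for t in sorted(ev.exclusion) if t in tpm.index]
        inc = tpm.loc[inc_ids].sum(axis=0) if inc_ids else pd.Series(0.0, index=samples)
        exc = tpm.loc[exc_ids].sum(axis=0) if exc_ids else pd.Series(0.0, index=samples)
        psi = {}
        for s in samples:
            denom = float(inc[s] + exc[s])
            psi[s] = float(inc[s]) / denom if denom > 0 else math.nan
        pooled_inc = {
            c: float(sum(inc[s] for s in samples if sample_conditions.get(s) == c))
            for c in conditions
        }
        pooled_exc = {
            c: float(sum(exc[s] for s in samples if sample_conditions.get(s) == c))
            for c in conditions
        }
        mean_psi = {}
        for c in conditions:
            vals = [
                psi[s]
                for s in samples
                if sample_conditions.get(s) == c and not math.isnan(psi[s])
            ]
            mean_psi[c] = float(np.mean(vals)) if vals else math.nan
        rec = PsiRecord(
            event_id=ev.event_id,
            gene_id=ev.gene_id,
            etype=ev.etype,
            novel=ev.novel,
            psi=psi,
            pooled_inclusion=pooled_inc,
            pooled_exclusion=pooled_exc,
            mean_psi=mean_psi,
        )
        rec.delta_psi = mean_psi[cond_treat] - mean_psi[cond_ctrl]
        records.append(rec)
    return records


def test_differential_events(
    psi_records: Sequence[PsiRecord],
    conditions: Tuple[str, str],
    count_scale: int = 100,
    fdr_threshold: float = 0.05,
) -> List[PsiRecord]:
    """Fisher exact test on condition x form pseudo-counts, BH-adjusted.

    Pseudo-counts split `count_scale` proportionally to the pooled
    inclusion/exclusion TPM of each condition.  Events with an undefined
    PSI in either condition are excluded from testing (significant=None).
    """
    cond_ctrl, cond_treat = conditions
    testable = []
    for rec in psi_records:
        tot_c = rec.pooled_inclusion[cond_ctrl] + rec.pooled_exclusion[cond_ctrl]
        tot_t = rec.pooled_inclusion[cond_treat] + rec.pooled_exclusion[cond_treat]
        if tot_c <= 0 or tot_t <= 0 or math.isnan(rec.delta_psi):
            rec.significant = None
            continue
        inc_c = round(count_scale * rec.pooled_inclusion[cond_ctrl] / tot_c)
        inc_t = round(count_scale * rec.pooled_inclusion[cond_treat] / tot_t)
        table = [[inc_c, count_scale - inc_c], [inc_t, count_scale - inc_t]]
        if sum(table[0]) + sum(table[1]) == 0:
            rec.significant = None
            continue
        rec.p_value = fisher_exact_2x2(table)
        testable.append(rec)
    if testable:
        adjusted = bh_adjust([r.p_value for r in testable])
        for rec, padj in zip(testable, adjusted):
            rec.adjusted_p = padj
            rec.significant = padj < fdr_threshold
    return list(psi_records)
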