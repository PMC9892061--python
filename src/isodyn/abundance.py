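"""FLNC-based isoform abundance and between-condition usage dynamics.

Isoform abundance is the fraction of a gene's FLNC reads supporting the
isoform.  Within each gene and condition the largest-fraction isoform is
the major isoform, isoforms with abundance < 0.1 are inactive, and the
rest are minor.  Between conditions an isoform's status is up or down when
|delta abundance| >= 0.1 (inclusive), else unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import pandas as pd

from .models import Annotation, DataError
from .validation import FlncAssignment

CLASSES = ("major", "minor", "inactive")


@dataclass
class AbundanceRecord:
    transcript_id: str
    gene_id: str
    condition: str
    abundance: float
    klass: str
    flnc_count: int


@dataclass
class IsoformDynamics:
    transcript_id: str
    gene_id: str
    abundance_ctrl: float
    abundance_treat: float
    delta: float
    status: str  # up / down / unchanged
    state_pair: Tuple[str, str]


def compute_abundance(
    assignment: FlncAssignment,
    annotation: Annotation,
    condition: str,
    inactive_threshold: float = 0.1,
) -> List[AbundanceRecord]:
    """Per-isoform FLNC fraction within its gene, with major/minor/inactive class.

    Genes with zero FLNC reads in the condition get all isoforms inactive at
    abundance 0.  The major tie-break is larger raw FLNC count, then
    lexicographically smaller transcript id.
    """
    records: List[AbundanceRecord] = []
    for gene_id in sorted(annotation.genes):
        tids = annotation.genes[gene_id]
        counts = {tid: assignment.count(tid, condition) for tid in tids}
        total = sum(counts.values())
        if total == 0:
            for tid in tids:
                records.append(
                    AbundanceRecord(tid, gene_id, condition, 0.0, "inactive", 0)
                )
            continue
        major = max(tids, key=lambda t: (counts[t], _neg_id_key(t)))
        for tid in tids:
            ab = counts[tid] / total
            if tid == major:
                klass = "major"
            elif ab < inactive_threshold:
                klass = "inactive"
            else:
                klass = "minor"
            records.append(
                AbundanceRecord(tid, gene_id, condition, ab, klass, counts[tid])
            )
    return records


class _neg_id_key:
    """Reverses lexicographic order so max() prefers the smaller id."""

    __slots__ = ("s",)

    def __init__(self, s: str):
        self.s = s

    def __lt__(self, other: "_neg_id_key") -> bool:
        return self.s > other.s

    def __eq__(self, other) -> bool:
        return self.s == other.s


def compare_usage(
    ctrl: Sequence[AbundanceRecord],
    treat: Sequence[AbundanceRecord],
    delta_threshold: float = 0.1,
) -> Tuple[List[IsoformDynamics], pd.DataFrame]:
    """Per-isoform delta abundance, status, and the 3x3 class-transition table."""
    ctrl_by_id = {r.transcript_id: r for r in ctrl}
    treat_by_id = {r.transcript_id: r for r in treat}
    missing = sorted(set(ctrl_by_id) ^ set(treat_by_id))
    if missing:
        raise DataError(
            f"transcript universes differ between conditions; mismatched ids: {missing[:10]}"
        )
    dynamics: List[IsoformDynamics] = []
    table = pd.DataFrame(0, index=list(CLASSES), columns=list(CLASSES))
    eps = 1e-9  # keeps the inclusive boundary inclusive under float subtraction
    for tid in sorted(ctrl_by_id):
        a, b = ctrl_by_id[tid], treat_by_id[tid]
        delta = b.abundance - a.abundance
        if delta >= delta_threshold - eps:
            status = "up"
        elif delta <= -(delta_threshold - eps):
            status = "down"
        else:
            status = "unchanged"
        dynamics.append(
            IsoformDynamics(
                transcript_id=tid,
                gene_id=a.gene_id,
                abundance_ctrl=a.abundance,
                abundance_treat=b.abundance,
                delta=delta,
                status=status,
                state_pair=(a.klass, b.klass),
            )
        )
        table.loc[a.klass, b.klass] += 1
    return dynamics, table


def changed_usage_fraction(
    n_up: int, n_down: int, n_total: int, n_inactive_both: int
) -> float:
    """Percent of non-(always-inactive) isoforms whose usage changed, 1 decimal."""
    denom = n_total - n_inactive_both
    if denom <= 0:
        raise DataError("denominator (total - inactive in both) must be positive")
    return round(100.0 * (n_up + n_down) / denom, 1)
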