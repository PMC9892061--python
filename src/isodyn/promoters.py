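"""Promoter definition from first junctions and differential promoter calling.

A promoter is the group of a gene's multi-exon transcripts that share the
same strand-aware first intron; its activity in a sample is the size-factor
normalized count of short reads spanning that intron, and relative activity
is the within-gene fraction.  Differentially regulated promoters (DRPs)
pass fold-change and FDR gates on pooled per-condition counts; alternative
promoters (APs) additionally require a relative-activity shift and an
expressed gene; a gene with APs in both directions is a switching gene.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .models import Annotation, DataError, Interval
from .stats import bh_adjust, binomial_rate_test, log2_fold_change


@dataclass
class Promoter:
    promoter_id: str
    gene_id: str
    chrom: str
    strand: str
    first_intron: Interval
    members: Tuple[str, ...]
    known: bool


@dataclass
class PromoterActivity:
    promoter_id: str
    gene_id: str
    absolute: Dict[str, float]   # sample -> normalized first-junction count
    relative: Dict[str, float]   # sample -> within-gene fraction
    mean_relative: float
    klass: str                   # major / minor / inactive


def define_promoters(
    isoforms: Annotation, reference: Annotation
) -> Tuple[List[Promoter], Dict[str, int]]:
    """Group multi-exon transcripts per gene by first intron.

    Mono-exon transcripts are excluded (junction-based activity is undefined
    for them).  A promoter is known when some reference transcript uses the
    same first intron on the same chrom/strand.
    """
    ref_first_introns = set()
    for t in reference:
        fi = t.first_intron
        if fi is not None:
            ref_first_introns.add((t.chrom, t.strand, fi))

    promoters: List[Promoter] = []
    gene_promoter_count: Dict[str, int] = {}
    for gene_id in sorted(isoforms.genes):
        groups: Dict[Tuple, List[str]] = {}
        for t in isoforms.gene_transcripts(gene_id):
            fi = t.first_intron
            if fi is None:
                continue
            groups.setdefault((t.chrom, t.strand, fi), []).append(t.transcript_id)
        if not groups:
            continue
        # order promoters 5'->3' along the gene
        keys = sorted(
            groups,
            key=lambda k: (k[2][0] if k[1] == "+" else -k[2][1]),
        )
        gene_promoter_count[gene_id] = len(keys)
        for i, key in enumerate(keys, start=1):
            chrom, strand, fi = key
            promoters.append(
                Promoter(
                    promoter_id=f"{gene_id}.p{i}",
                    gene_id=gene_id,
                    chrom=chrom,
                    strand=strand,
                    first_intron=fi,
                    members=tuple(sorted(groups[key])),
                    known=key in ref_first_introns,
                )
            )
    counts = {
        "single_promoter_genes": sum(1 for n in gene_promoter_count.values() if n == 1),
        "multi_promoter_genes": sum(1 for n in gene_promoter_count.values() if n > 1),
    }
    return promoters, counts


def junction_count_index(junction_table: pd.DataFrame) -> Dict[Tuple, Dict[str, int]]:
    """(chrom, start, end, strand) -> {sample: count} from a junction count table."""
    index: Dict[Tuple, Dict[str, int]] = {}
    for row in junction_table.itertuples(index=False):
        key = (row.chrom, int(row.start), int(row.end), row.strand)
        index.setdefault(key, {})[row.sample] = index.setdefault(key, {}).get(
            row.sample, 0
        ) + int(row.count)
    return index


def default_size_factors(junction_table: pd.DataFrame) -> Dict[str, float]:
    """Per-sample total junction counts, scaled to mean 1."""
    totals = junction_table.groupby("sample")["count"].sum()
    mean = float(totals.mean())
    if mean <= 0:
        raise DataError("junction table has no reads")
    return {s: float(v) / mean for s, v in totals.items()}


def compute_promoter_activity(
    promoters: Sequence[Promoter],
    junction_table: pd.DataFrame,
    size_factors: Optional[Mapping[str, float]] = None,
    inactive_threshold: float = 0.1,
) -> List[PromoterActivity]:
    """Absolute and relative promoter activity per sample, with class labels.

    Class comes from the mean relative activity across all samples: the
    highest mean in the gene is major (ties: larger absolute-activity sum,
    then id), below `inactive_threshold` is inactive, the rest minor.
    """
    if size_factors is None:
        size_factors = default_size_factors(junction_table)
    for sf in size_factors.values():
        if sf <= 0:
            raise DataError("size factors must be positive")
    samples = sorted(size_factors)
    jc = junction_count_index(junction_table)

    by_gene: Dict[str, List[Promoter]] = {}
    for p in promoters:
        by_gene.setdefault(p.gene_id, []).append(p)

    activities: List[PromoterActivity] = []
    for gene_id in sorted(by_gene):
        gene_proms = by_gene[gene_id]
        absolute: Dict[str, Dict[str, float]] = {}
        for p in gene_proms:
            key = (p.chrom, p.first_intron[0], p.first_intron[1], p.strand)
            counts = jc.get(key, {})
            absolute[p.promoter_id] = {
                s: counts.get(s, 0) / size_factors[s] for s in samples
            }
        gene_totals = {
            s: sum(absolute[p.promoter_id][s] for p in gene_proms) for s in samples
        }
        relative = {
            p.promoter_id: {
                s: (absolute[p.promoter_id][s] / gene_totals[s]) if gene_totals[s] > 0 else 0.0
                for s in samples
            }
            for p in gene_proms
        }
        mean_rel = {
            p.promoter_id: float(np.mean([relative[p.promoter_id][s] for s in samples]))
            for p in gene_proms
        }
        major = max(
            gene_proms,
            key=lambda p: (
                mean_rel[p.promoter_id],
                sum(absolute[p.promoter_id].values()),
                _rev(p.promoter_id),
            ),
        ).promoter_id
        for p in gene_proms:
            if p.promoter_id == major:
                klass = "major"
            elif mean_rel[p.promoter_id] < inactive_threshold:
                klass = "inactive"
            else:
                klass = "minor"
            activities.append(
                PromoterActivity(
                    promoter_id=p.promoter_id,
                    gene_id=gene_id,
                    absolute=absolute[p.promoter_id],
                    relative=relative[p.promoter_id],
                    mean_relative=mean_rel[p.promoter_id],
                    klass=klass,
                )
            )
    return activities


class _rev:
    __slots__ = ("s",)

    def __init__(self, s: str):
        self.s = s

    def __lt__(self, other) -> bool:
        return self.s > other.s

    def __eq__(self, other) -> bool:
        return self.s == other.s


def test_differential_promoters(
    promoters: Sequence[Promoter],
    junction_table: pd.DataFrame,
    sample_conditions: Mapping[str, str],
    conditions: Tuple[str, str],
    fc_threshold: float = 1.5,
    fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """Exact conditioned-binomial test of pooled first-junction counts.

    Size factors are the per-condition total junction counts.  Returns one
    row per promoter with pooled counts, log2 fold change (treat vs ctrl),
    p, BH-adjusted p, and the DRP flag (|FC| > fc_threshold and adjusted
    p < fdr_threshold).  Promoters with zero pooled counts in both
    conditions are reported with NA statistics.
    """
    cond_ctrl, cond_treat = conditions
    jc = junction_count_index(junction_table)
    cond_totals = {cond_ctrl: 0, cond_treat: 0}
    for row in junction_table.itertuples(index=False):
        cond = sample_conditions.get(row.sample)
        if cond in cond_totals:
            cond_totals[cond] += int(row.count)
    if cond_totals[cond_ctrl] <= 0 or cond_totals[cond_treat] <= 0:
        raise DataError("each condition needs at least one junction read")
    # scale size factors to mean 1 so normalized counts stay on the count
    # scale and the fold-change pseudocount keeps its intended weight
    mean_total = (cond_totals[cond_ctrl] + cond_totals[cond_treat]) / 2.0
    size = {c: cond_totals[c] / mean_total for c in cond_totals}

    rows = []
    for p in promoters:
        key = (p.chrom, p.first_intron[0], p.first_intron[1], p.strand)
        counts = jc.get(key, {})
        k_ctrl = sum(
            c for s, c in counts.items() if sample_conditions.get(s) == cond_ctrl
        )
        k_treat = sum(
            c for s, c in counts.items() if sample_conditions.get(s) == cond_treat
        )
        if k_ctrl + k_treat == 0:
            rows.append((p.promoter_id, p.gene_id, p.known, 0, 0, math.nan, math.nan))
            continue
        lfc = log2_fold_change(k_treat, k_ctrl, size[cond_treat], size[cond_ctrl])
        pval = binomial_rate_test(
            k_treat, k_ctrl, cond_totals[cond_treat], cond_totals[cond_ctrl]
        )
        rows.append((p.promoter_id, p.gene_id, p.known, k_ctrl, k_treat, lfc, pval))
    df = pd.DataFrame(
        rows,
        columns=[
            "promoter_id", "gene_id", "known",
            "count_ctrl", "count_treat", "log2fc", "p_value",
        ],
    )
    tested = df["p_value"].notna()
    adjusted = pd.Series(math.nan, index=df.index)
    if tested.any():
        adjusted.loc[tested] = bh_adjust(df.loc[tested, "p_value"].tolist())
    df["adjusted_p"] = adjusted
    lfc_gate = df["log2fc"].abs() > math.log2(fc_threshold)
    df["is_drp"] = tested & lfc_gate & (df["adjusted_p"] < fdr_threshold)
    return df


def call_alternative_promoters(
    drp_table: pd.DataFrame,
    activities: Sequence[PromoterActivity],
    gene_fpkm: pd.DataFrame,
    sample_conditions: Mapping[str, str],
    conditions: Tuple[str, str],
    rel_min: float = 0.1,
    delta_rel: float = 0.1,
    fpkm_min: float = 1.0,
) -> Tuple[pd.DataFrame, List[str]]:
    """Alternative promoters and switching genes.

    A promoter is an AP when its mean relative activity exceeds `rel_min` in
    at least one condition, its between-condition relative-activity shift
    exceeds `delta_rel`, it passes the DRP gates, and its gene's FPKM
    exceeds `fpkm_min` in at least one condition.  Direction is the sign of
    the promoter's expression log2 fold change; a gene with APs in both
    directions is a switching gene.

    `gene_fpkm` must be indexed by gene_id with one fpkm column per
    condition (named after the condition labels).
    """
    cond_ctrl, cond_treat = conditions
    act_by_id = {a.promoter_id: a for a in activities}
    missing_fpkm: List[str] = []

    def cond_mean_rel(a: PromoterActivity, cond: str) -> float:
        vals = [v for s, v in a.relative.items() if sample_conditions.get(s) == cond]
        return float(np.mean(vals)) if vals else 0.0

    rows = []
    for row in drp_table.itertuples(index=False):
        a = act_by_id.get(row.promoter_id)
        if a is None or not bool(row.is_drp):
            continue
        if a.gene_id not in gene_fpkm.index:
            missing_fpkm.append(a.gene_id)
            continue
        fpkms = gene_fpkm.loc[a.gene_id]
        if not (fpkms.get(cond_ctrl, 0.0) > fpkm_min or fpkms.get(cond_treat, 0.0) > fpkm_min):
            continue
        rel_ctrl = cond_mean_rel(a, cond_ctrl)
        rel_treat = cond_mean_rel(a, cond_treat)
        if max(rel_ctrl, rel_treat) <= rel_min:
            continue
        if abs(rel_treat - rel_ctrl) <= delta_rel:
            continue
        direction = "up" if row.log2fc > 0 else "down"
        rows.append(
            (
                row.promoter_id, a.gene_id, rel_ctrl, rel_treat,
                rel_treat - rel_ctrl, row.log2fc, row.adjusted_p, direction,
            )
        )
    ap = pd.DataFrame(
        rows,
        columns=[
            "promoter_id", "gene_id", "rel_ctrl", "rel_treat",
            "delta_rel", "log2fc", "adjusted_p", "direction",
        ],
    )
    switching: List[str] = []
    if len(ap):
        for gene_id, grp in ap.groupby("gene_id"):
            dirs = set(grp["direction"])
            if {"up", "down"} <= dirs:
                switching.append(str(gene_id))
    return ap, sorted(switching)
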