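"""End-to-end orchestration: pools -> support/dedup -> classification ->
abundance -> promoters -> splicing -> APA, driven by one configuration.

Each stage writes its outputs before the next starts; the consolidated
summary JSON carries per-stage counts plus the headline quantities
(support rates, category percentages, changed-usage percentage, AP/AS/APA
call counts).  Runs are deterministic for identical inputs and config.
"""

from __future__ import annotations

import dataclasses
import difflib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Tuple

import pandas as pd

from . import abundance as ab
from . import apa as apa_mod
from . import classify as cls_mod
from . import promoters as prom_mod
from . import splicing as spl_mod
from . import validation as val_mod
from .io import (
    read_annotation,
    read_coverage,
    read_flnc_counts,
    read_genome,
    read_intervals,
    read_junction_counts,
    read_table,
    read_tpm,
    write_table,
)
from .models import Annotation, DataError, IsodynError

logger = logging.getLogger("isodyn")


class ConfigError(IsodynError):
    """Invalid pipeline configuration."""


@dataclass
class PipelineConfig:
    # input paths
    genome: str = ""
    reference_gtf: str = ""
    isoforms_gtf: str = ""
    cage_bed: str = ""
    pas_bed: str = ""
    junctions_tsv: str = ""
    flnc_counts_tsv: str = ""
    tpm_tsv: str = ""
    gene_expression_tsv: str = ""
    coverage_ctrl: str = ""
    coverage_treat: str = ""
    outdir: str = "isodyn_out"
    # condition labels; samples are mapped to a condition by name prefix
    # "<condition>_" unless sample_conditions is given explicitly
    conditions: Tuple[str, str] = ("control", "treated")
    sample_conditions: Dict[str, str] = field(default_factory=dict)
    # stage thresholds
    end_window: int = 50
    min_junction_reads: int = 2
    min_pas_reads: int = 5
    inactive_threshold: float = 0.1
    delta_abundance: float = 0.1
    fc_threshold: float = 1.5
    fdr_threshold: float = 0.05
    rel_min: float = 0.1
    delta_rel: float = 0.1
    fpkm_min: float = 1.0
    count_scale: int = 100
    min_delta_pdui: float = 0.2
    read_length: int = 150
    pas_cluster_window: int = 50
    ip_exempt_fsm: bool = True
    seed: int = 0

    def __post_init__(self):
        positive = (
            "end_window", "min_junction_reads", "min_pas_reads",
            "inactive_threshold", "delta_abundance", "fc_threshold",
            "fdr_threshold", "rel_min", "delta_rel", "count_scale",
            "min_delta_pdui", "read_length", "pas_cluster_window",
        )
        for name in positive:
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if len(self.conditions) != 2:
            raise ConfigError("exactly two condition labels are required")

    def condition_of(self, sample: str) -> Optional[str]:
        if sample in self.sample_conditions:
            return self.sample_conditions[sample]
        for cond in self.conditions:
            if sample.startswith(f"{cond}_") or sample == cond:
                return cond
        return None


def validate_config(path) -> PipelineConfig:
    """Load a JSON config file, fill defaults, reject unknown keys."""
    try:
        text = Path(path).read_text()
    except OSError as exc:
        raise ConfigError(f"cannot read config {path}: {exc}") from exc
    payload = json.loads(text) if text.strip() else {}
    if not isinstance(payload, dict):
        raise ConfigError("config must be a JSON object")
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = [k for k in payload if k not in known]
    if unknown:
        hints = []
        for k in unknown:
            close = difflib.get_close_matches(k, known, n=1)
            hints.append(f"{k!r}" + (f" (did you mean {close[0]!r}?)" if close else ""))
        raise ConfigError("unknown config key(s): " + ", ".join(hints))
    if "conditions" in payload:
        payload["conditions"] = tuple(payload["conditions"])
    try:
        config = PipelineConfig(**payload)
    except TypeError as exc:
        raise ConfigError(f"bad config value types: {exc}") from exc
    logger.info("effective config: %s", dataclasses.asdict(config))
    return config


def _stage(name: str):
    logger.info("stage: %s", name)


def run_pipeline(config: PipelineConfig) -> Dict:
    """Execute all stages in order; returns (and writes) the summary."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cond_ctrl, cond_treat = config.conditions
    summary: Dict = {"config": dataclasses.asdict(config), "stages": {}}

    def fail(stage: str, exc: Exception):
        raise DataError(f"stage {stage}: {exc}") from exc

    # ---- load inputs ----
    _stage("load")
    try:
        genome = read_genome(config.genome) if config.genome else None
        reference = read_annotation(config.reference_gtf)
        isoforms = read_annotation(config.isoforms_gtf)
        cage = read_intervals(config.cage_bed)
        pas_reads = read_intervals(config.pas_bed)
        junctions = read_junction_counts(config.junctions_tsv)
        flnc_table = read_flnc_counts(config.flnc_counts_tsv)
        tpm = read_tpm(config.tpm_tsv)
        gene_fpkm = read_table(config.gene_expression_tsv, ["gene_id"]).set_index("gene_id")
    except (OSError, DataError) as exc:
        fail("load", exc)

    sample_conditions = {}
    for s in list(tpm.columns) + sorted(junctions["sample"].unique()):
        cond = config.condition_of(str(s))
        if cond is not None:
            sample_conditions[str(s)] = cond

    # ---- evidence pools ----
    _stage("pools")
    pools = val_mod.build_evidence_pools(
        cage, pas_reads, [junctions], reference, min_pas_reads=config.min_pas_reads
    )

    # ---- support + dedup ----
    _stage("validate")
    reports = [
        val_mod.evaluate_support(
            t, pools, end_window=config.end_window,
            min_junction_reads=config.min_junction_reads,
        )
        for t in sorted(isoforms, key=lambda t: t.transcript_id)
    ]
    rates = val_mod.summarize_support(reports)
    kept, dedup_map = val_mod.deduplicate_by_tss(
        list(isoforms), pools, pas_window=config.end_window
    )
    write_table(
        pd.DataFrame(
            [
                (
                    r.transcript_id, r.tss_supported, r.tss_distance,
                    r.pas_supported, r.pas_distance,
                    all(ok for (_, ok, _) in r.junctions), r.fully_supported,
                )
                for r in reports
            ],
            columns=[
                "transcript_id", "tss_supported", "tss_distance",
                "pas_supported", "pas_distance", "junctions_supported",
                "fully_supported",
            ],
        ),
        outdir / "support_report.tsv",
    )
    write_table(
        pd.DataFrame(sorted(dedup_map.items()), columns=["dropped", "kept"]),
        outdir / "dedup_map.tsv",
    )
    summary["stages"]["validate"] = {
        "n_isoforms": len(isoforms),
        "n_kept_after_dedup": len(kept),
        "support_rates": rates,
    }

    # ---- classification + internal-priming filter ----
    _stage("classify")
    catalog = Annotation(kept)
    calls = cls_mod.classify_catalog(catalog, reference, genome)
    cat_summary = cls_mod.summarize_structural_categories(calls)
    flagged = {
        c.transcript_id
        for c in calls
        if c.internal_priming and not (config.ip_exempt_fsm and c.category == "FSM")
    }
    retained = Annotation([t for t in kept if t.transcript_id not in flagged])
    write_table(
        pd.DataFrame(
            [
                (c.transcript_id, c.category, c.matched_reference_id or "",
                 c.internal_priming)
                for c in calls
            ],
            columns=["transcript_id", "category", "matched_reference_id",
                     "internal_priming"],
        ),
        outdir / "classification.tsv",
    )
    summary["stages"]["classify"] = {
        "categories": cat_summary,
        "n_internal_priming_removed": len(flagged),
        "n_retained": len(retained),
    }

    # ---- FLNC assignment + abundance dynamics ----
    _stage("abundance")
    assignment = val_mod.FlncAssignment.from_count_table(
        flnc_table[flnc_table["transcript_id"].isin(retained.transcripts)]
    )
    # reads of deduplicated isoforms follow their keeper
    for row in flnc_table[~flnc_table["transcript_id"].isin(retained.transcripts)].itertuples(index=False):
        keeper = dedup_map.get(row.transcript_id)
        if keeper is not None and keeper in retained.transcripts:
            assignment.add(keeper, row.sample, int(row.count))
    ab_ctrl = ab.compute_abundance(
        assignment, retained, cond_ctrl, inactive_threshold=config.inactive_threshold
    )
    ab_treat = ab.compute_abundance(
        assignment, retained, cond_treat, inactive_threshold=config.inactive_threshold
    )
    dynamics, transitions = ab.compare_usage(
        ab_ctrl, ab_treat, delta_threshold=config.delta_abundance
    )
    n_up = sum(1 for d in dynamics if d.status == "up")
    n_down = sum(1 for d in dynamics if d.status == "down")
    n_inactive_both = int(transitions.loc["inactive", "inactive"])
    changed_pct = (
        ab.changed_usage_fraction(n_up, n_down, len(dynamics), n_inactive_both)
        if len(dynamics) > n_inactive_both
        else 0.0
    )
    for records, name in ((ab_ctrl, cond_ctrl), (ab_treat, cond_treat)):
        write_table(
            pd.DataFrame(
                [(r.transcript_id, r.gene_id, r.abundance, r.klass, r.flnc_count)
                 for r in records],
                columns=["transcript_id", "gene_id", "abundance", "class", "flnc_count"],
            ),
            outdir / f"abundance_{name}.tsv",
        )
    write_table(
        pd.DataFrame(
            [(d.transcript_id, d.gene_id, d.abundance_ctrl, d.abundance_treat,
              d.delta, d.status, d.state_pair[0], d.state_pair[1])
             for d in dynamics],
            columns=["transcript_id", "gene_id", "abundance_ctrl",
                     "abundance_treat", "delta", "status", "class_ctrl",
                     "class_treat"],
        ),
        outdir / "dynamics.tsv",
    )
    transitions.to_csv(outdir / "transition_table.tsv", sep="\t")
    summary["stages"]["abundance"] = {
        "n_up": n_up,
        "n_down": n_down,
        "n_inactive_both": n_inactive_both,
        "changed_usage_percent": changed_pct,
        "transition_grand_total": int(transitions.values.sum()),
    }

    # ---- promoters ----
    _stage("promoters")
    proms, prom_counts = prom_mod.define_promoters(retained, reference)
    activities = prom_mod.compute_promoter_activity(
        proms, junctions, inactive_threshold=config.inactive_threshold
    )
    drp = prom_mod.test_differential_promoters(
        proms, junctions, sample_conditions, config.conditions,
        fc_threshold=config.fc_threshold, fdr_threshold=config.fdr_threshold,
    )
    ap_calls, switching = prom_mod.call_alternative_promoters(
        drp, activities, gene_fpkm, sample_conditions, config.conditions,
        rel_min=config.rel_min, delta_rel=config.delta_rel,
        fpkm_min=config.fpkm_min,
    )
    write_table(
        pd.DataFrame(
            [(p.promoter_id, p.gene_id, p.chrom, p.strand,
              p.first_intron[0], p.first_intron[1], p.known,
              ",".join(p.members))
             for p in proms],
            columns=["promoter_id", "gene_id", "chrom", "strand",
                     "intron_start", "intron_end", "known", "members"],
        ),
        outdir / "promoters.tsv",
    )
    write_table(
        pd.DataFrame(
            [(a.promoter_id, a.gene_id, a.mean_relative, a.klass)
             for a in activities],
            columns=["promoter_id", "gene_id", "mean_relative", "class"],
        ),
        outdir / "promoter_activity.tsv",
    )
    write_table(drp, outdir / "drp.tsv")
    write_table(ap_calls, outdir / "alternative_promoters.tsv")
    write_table(
        pd.DataFrame({"gene_id": switching}), outdir / "switching_genes.tsv"
    )
    summary["stages"]["promoters"] = {
        **prom_counts,
        "n_promoters": len(proms),
        "n_drp": int(drp["is_drp"].sum()),
        "n_ap": len(ap_calls),
        "n_switching_genes": len(switching),
    }

    # ---- splicing ----
    _stage("splicing")
    events = spl_mod.enumerate_events(retained, reference)
    psi_records = spl_mod.compute_psi(events, tpm, sample_conditions, config.conditions)
    psi_records = spl_mod.test_differential_events(
        psi_records, config.conditions, count_scale=config.count_scale,
        fdr_threshold=config.fdr_threshold,
    )
    write_table(
        pd.DataFrame(
            [(e.event_id, e.etype, e.gene_id, ",".join(sorted(e.inclusion)),
              ",".join(sorted(e.exclusion)), e.novel)
             for e in events],
            columns=["event_id", "type", "gene_id", "inclusion", "exclusion",
                     "novel"],
        ),
        outdir / "events.tsv",
    )
    write_table(
        pd.DataFrame(
            [(r.event_id, r.etype, r.mean_psi[cond_ctrl], r.mean_psi[cond_treat],
              r.delta_psi, r.p_value, r.adjusted_p, bool(r.significant))
             for r in psi_records],
            columns=["event_id", "type", "psi_ctrl", "psi_treat", "delta_psi",
                     "p_value", "adjusted_p", "significant"],
        ),
        outdir / "differential_events.tsv",
    )
    by_type = {t: sum(1 for e in events if e.etype == t) for t in spl_mod.EVENT_TYPES}
    summary["stages"]["splicing"] = {
        "n_events": len(events),
        "by_type": by_type,
        "n_significant": sum(1 for r in psi_records if r.significant),
    }

    # ---- APA ----
    _stage("apa")
    try:
        cov_ctrl = read_coverage(config.coverage_ctrl)
        cov_treat = read_coverage(config.coverage_treat)
    except (OSError, DataError) as exc:
        fail("apa", exc)
    pas_positions: Dict[Tuple[str, str], List[Tuple[int, int]]] = {}
    for t in retained:
        support = assignment.count(t.transcript_id, cond_ctrl) + assignment.count(
            t.transcript_id, cond_treat
        )
        pas_positions.setdefault((t.chrom, t.strand), []).append(
            (t.pas, max(support, 1))
        )
    clusters = apa_mod.cluster_pas_sites(pas_positions, window=config.pas_cluster_window)
    clusters = apa_mod.label_pas_clusters(clusters, reference, window=config.pas_cluster_window)
    regions = apa_mod.build_apa_regions(retained, clusters)
    pdui_records = apa_mod.test_differential_apa(
        regions, cov_ctrl, cov_treat,
        fdr_threshold=config.fdr_threshold, min_delta=config.min_delta_pdui,
        read_length=config.read_length,
    )
    if genome is not None and clusters:
        profile = apa_mod.pas_nucleotide_profile(clusters, genome)
        write_table(profile.reset_index(), outdir / "nucleotide_profile.tsv")
        signal_fraction = apa_mod.scan_polya_signal(clusters, genome)
    else:
        signal_fraction = math.nan
    write_table(
        pd.DataFrame(
            [(c.cluster_id, c.chrom, c.strand, c.representative, c.support,
              bool(c.known))
             for c in clusters],
            columns=["cluster_id", "chrom", "strand", "representative",
                     "support", "known"],
        ),
        outdir / "pas_clusters.tsv",
    )
    write_table(
        pd.DataFrame(
            [(r.gene_id, r.pdui_ctrl, r.pdui_treat, r.delta_pdui, r.p_value,
              r.adjusted_p, r.call)
             for r in pdui_records],
            columns=["gene_id", "pdui_ctrl", "pdui_treat", "delta_pdui",
                     "p_value", "adjusted_p", "call"],
        ),
        outdir / "differential_apa.tsv",
    )
    summary["stages"]["apa"] = {
        "n_pas_clusters": len(clusters),
        "n_known_clusters": sum(1 for c in clusters if c.known),
        "n_regions": len(regions),
        "n_shortened": sum(1 for r in pdui_records if r.call == "shortened"),
        "n_lengthened": sum(1 for r in pdui_records if r.call == "lengthened"),
        "polya_signal_fraction": signal_fraction,
    }

    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True, default=str)
        fh.write("\n")
    return summary
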