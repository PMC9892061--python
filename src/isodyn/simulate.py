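"""Two-condition synthetic transcriptome scenarios with planted effects.

The generator builds a small genome with non-overlapping multi-isoform
genes on both strands, realizes the structures each analysis stage needs
(multiple promoters, local splicing variants, tandem PAS pairs), plants
condition-specific isoform expression to drive promoter switches, PSI
shifts, PDUI shifts and abundance changes from one mechanism, and then
simulates every measurement the pipeline consumes: FLNC counts
(multinomial), junction counts (Poisson), TPM replicates (lognormal
noise), per-base coverage (Poisson around the uniform within-transcript
expectation), and 5'/3' end-evidence positions with Gaussian jitter plus
low-count decoy PAS sites.  A TruthManifest records every planted effect.

Upstream of every true PAS the genome carries the canonical AATAAA
hexamer at offset -20 and an A-enriched -25..-1 window; the 20 nt
downstream of a PAS are guaranteed not to look like internal priming.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .io import (
    BedRecord,
    write_annotation,
    write_coverage,
    write_genome,
    write_intervals,
    write_table,
)
from .models import (
    Annotation,
    CoverageTrack,
    DataError,
    GenomeSequence,
    TranscriptModel,
    reverse_complement,
)

CHROM = "chr1"
_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass(frozen=True)
class ScenarioConfig:
    """Study conditions for one synthetic scenario.

    Effect magnitudes are ctrl/treat parameter pairs; planted genes use the
    pair one way in control and swapped (or shifted) in treatment, null
    genes of the same structure keep it constant.
    """

    n_background_genes: int = 4
    n_abundance_genes: int = 4
    n_abundance_shift: int = 2
    abundance_levels: Tuple[float, float] = (0.65, 0.35)
    n_promoter_genes: int = 4
    n_ap_switch: int = 2
    promoter_activity: Tuple[float, float] = (0.8, 0.2)
    n_as_genes: int = 4
    n_as_shift: int = 2
    psi_levels: Tuple[float, float] = (0.7, 0.3)
    n_apa_genes: int = 4
    n_apa_shift: int = 2
    pdui_levels: Tuple[float, float] = (0.8, 0.4)
    fraction_novel_isoforms: float = 0.25
    flnc_depth_per_gene: int = 2000
    junction_depth_per_gene: float = 500.0
    coverage_depth: float = 50.0
    n_replicates: int = 3
    tpm_noise_sd: float = 0.2
    jitter_sd: float = 5.0
    n_decoy_pas: int = 20
    decoy_min_distance: int = 60
    min_pas_reads: int = 5
    gene_fpkm: float = 10.0
    intergenic_gap: int = 500
    conditions: Tuple[str, str] = ("control", "treated")
    seed: int = 0

    def __post_init__(self):
        for name in ("fraction_novel_isoforms",):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise DataError(f"{name} must be in [0, 1], got {v}")
        for name in ("flnc_depth_per_gene", "junction_depth_per_gene",
                     "coverage_depth", "n_replicates"):
            if getattr(self, name) < 1:
                raise DataError(f"{name} must be >= 1")
        for pair_name in ("abundance_levels", "promoter_activity",
                          "psi_levels", "pdui_levels"):
            a, b = getattr(self, pair_name)
            if not (0.0 <= a <= 1.0 and 0.0 <= b <= 1.0):
                raise DataError(f"{pair_name} entries must be in [0, 1]")
        if self.n_abundance_shift > self.n_abundance_genes:
            raise DataError("n_abundance_shift exceeds n_abundance_genes")
        if self.n_ap_switch > self.n_promoter_genes:
            raise DataError("n_ap_switch exceeds n_promoter_genes")
        if self.n_as_shift > self.n_as_genes:
            raise DataError("n_as_shift exceeds n_as_genes")
        if self.n_apa_shift > self.n_apa_genes:
            raise DataError("n_apa_shift exceeds n_apa_genes")
        if self.jitter_sd < 0 or self.n_decoy_pas < 0:
            raise DataError("jitter_sd and n_decoy_pas must be non-negative")

    @property
    def n_genes(self) -> int:
        return (
            self.n_background_genes
            + self.n_abundance_genes
            + self.n_promoter_genes
            + self.n_as_genes
            + self.n_apa_genes
        )

    @property
    def samples(self) -> Dict[str, List[str]]:
        return {
            cond: [f"{cond}_{r + 1}" for r in range(self.n_replicates)]
            for cond in self.conditions
        }

    @property
    def sample_conditions(self) -> Dict[str, str]:
        return {s: c for c, ss in self.samples.items() for s in ss}


@dataclass
class TruthManifest:
    """Ground truth for every planted effect, serializable losslessly."""

    conditions: Tuple[str, str]
    effects: List[dict] = field(default_factory=list)
    nulls: Dict[str, List[str]] = field(default_factory=dict)

    def of_type(self, effect_type: str) -> List[dict]:
        return [e for e in self.effects if e["type"] == effect_type]

    def to_json(self, path) -> None:
        payload = {
            "conditions": list(self.conditions),
            "effects": self.effects,
            "nulls": self.nulls,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "TruthManifest":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            conditions=tuple(payload["conditions"]),
            effects=payload["effects"],
            nulls=payload["nulls"],
        )


@dataclass
class SyntheticModels:
    genome: GenomeSequence
    reference: Annotation
    isoforms: Annotation
    expression: Dict[str, Tuple[float, float]]  # tid -> (x_ctrl, x_treat), per-gene fractions
    manifest: TruthManifest
    config: ScenarioConfig


# --- structure templates ('+' orientation, relative coordinates) --------------

def _template(kind: str) -> List[List[Tuple[int, int]]]:
    """Exon chains per isoform for one gene archetype."""
    if kind == "SE":
        return [[(0, 200), (500, 700), (1000, 1200)], [(0, 200), (1000, 1200)]]
    if kind == "A5":
        return [[(0, 250), (500, 700)], [(0, 200), (500, 700)]]
    if kind == "A3":
        return [[(0, 200), (500, 700)], [(0, 200), (550, 700)]]
    if kind == "MX":
        return [
            [(0, 200), (400, 500), (1000, 1200)],
            [(0, 200), (700, 800), (1000, 1200)],
        ]
    if kind == "IR":
        return [[(0, 700), (1000, 1200)], [(0, 200), (500, 700), (1000, 1200)]]
    if kind == "AF":
        return [
            [(0, 200), (800, 1000), (1300, 1500)],
            [(400, 600), (800, 1000), (1300, 1500)],
        ]
    if kind == "AL":
        return [[(0, 200), (500, 700)], [(0, 200), (800, 1000)]]
    if kind == "APA":
        return [[(0, 200), (500, 1600)], [(0, 200), (500, 1100)]]  # distal first
    if kind == "PROM":
        return [
            [(0, 200), (1000, 1200), (1500, 1700)],
            [(500, 700), (1000, 1200), (1500, 1700)],
        ]
    if kind == "MONO":
        return [[(0, 800)]]
    if kind == "SIMPLE":
        return [[(0, 200), (500, 700)]]
    raise DataError(f"unknown template {kind!r}")


_BACKGROUND_CYCLE = ("SE", "A5", "A3", "MX", "IR", "AF", "AL", "MONO", "SIMPLE")


def _mirror(exons: Sequence[Tuple[int, int]], span: int) -> List[Tuple[int, int]]:
    return sorted((span - e, span - s) for s, e in exons)


@dataclass
class _GenePlan:
    gene_id: str
    kind: str          # archetype label
    template: str      # structure template name
    strand: str
    origin: int
    span: int
    transcripts: List[TranscriptModel]
    x_ctrl: List[float]
    x_treat: List[float]


def _plan_genes(config: ScenarioConfig, rng: np.random.Generator) -> List[_GenePlan]:
    plans: List[_GenePlan] = []
    origin = config.intergenic_gap
    idx = 0

    def add(kind: str, template: str, x_ctrl: List[float], x_treat: List[float]):
        nonlocal origin, idx
        chains = _template(template)
        if len(chains) != len(x_ctrl):
            # single-isoform templates carry one expression weight
            x_ctrl = x_ctrl[: len(chains)]
            x_treat = x_treat[: len(chains)]
        span = max(e for chain in chains for _, e in chain)
        strand = "+" if idx % 2 == 0 else "-"
        gene_id = f"g{idx:04d}_{kind}"
        transcripts = []
        for k, chain in enumerate(chains, start=1):
            exons = chain if strand == "+" else _mirror(chain, span)
            transcripts.append(
                TranscriptModel(
                    transcript_id=f"{gene_id}.t{k}",
                    gene_id=gene_id,
                    chrom=CHROM,
                    strand=strand,
                    exons=tuple(sorted(exons)),
                )
            )
        # shift to genomic origin
        placed = [
            TranscriptModel(
                t.transcript_id,
                t.gene_id,
                t.chrom,
                t.strand,
                tuple((s + origin, e + origin) for s, e in t.exons),
            )
            for t in transcripts
        ]
        plans.append(
            _GenePlan(gene_id, kind, template, strand, origin, span, placed,
                      list(x_ctrl), list(x_treat))
        )
        origin += span + config.intergenic_gap
        idx += 1

    a, b = config.abundance_levels
    for i in range(config.n_abundance_genes):
        if i < config.n_abundance_shift:
            add("abund", "SE", [a, b], [b, a])
        else:
            add("abundnull", "SE", [0.6, 0.4], [0.6, 0.4])
    hi, lo = config.promoter_activity
    for i in range(config.n_promoter_genes):
        if i < config.n_ap_switch:
            add("apsw", "PROM", [hi, lo], [lo, hi])
        else:
            add("apnull", "PROM", [0.6, 0.4], [0.6, 0.4])
    p_c, p_t = config.psi_levels
    for i in range(config.n_as_genes):
        if i < config.n_as_shift:
            add("asshift", "SE", [p_c, 1 - p_c], [p_t, 1 - p_t])
        else:
            add("asnull", "SE", [0.5, 0.5], [0.5, 0.5])
    d_c, d_t = config.pdui_levels
    for i in range(config.n_apa_genes):
        if i < config.n_apa_shift:
            add("apashift", "APA", [d_c, 1 - d_c], [d_t, 1 - d_t])
        else:
            add("apanull", "APA", [0.6, 0.4], [0.6, 0.4])
    for i in range(config.n_background_genes):
        template = _BACKGROUND_CYCLE[i % len(_BACKGROUND_CYCLE)]
        n_iso = len(_template(template))
        x = [0.6, 0.4][:n_iso] if n_iso == 2 else [1.0]
        add("bg", template, list(x), list(x))
    return plans


def _plant_pas_context(
    seq: np.ndarray,
    pas: int,
    strand: str,
    rng: np.random.Generator,
    upstream: int = 25,
    downstream: int = 20,
) -> None:
    """Write an A-rich upstream window with AATAAA at -20 and a clean
    (non-internal-priming) downstream window around one PAS."""
    up = np.where(
        rng.random(upstream) < 0.6,
        np.frombuffer(b"A", dtype="S1")[0],
        _BASES[rng.integers(1, 4, size=upstream)],  # C/G/T
    ).astype("S1")
    up[5:11] = np.frombuffer(b"AATAAA", dtype="S1")
    while True:
        down = _BASES[rng.integers(0, 4, size=downstream)]
        s = down.tobytes().decode()
        if "AAAAAA" not in s and s.count("A") / downstream <= 0.6:
            break
    window = np.concatenate([up, down])
    if strand == "+":
        seq[pas - upstream:pas + downstream] = window
    else:
        rc = np.frombuffer(
            reverse_complement(window.tobytes().decode()).encode(), dtype="S1"
        )
        seq[pas - downstream:pas + upstream] = rc


def build_gene_models(
    config: ScenarioConfig, seed: Optional[int] = None
) -> SyntheticModels:
    """Genome, reference annotation, isoform catalog and truth manifest.

    Deterministic given (config, seed).  A `fraction_novel_isoforms` share
    of the catalog is withheld from the reference (at least one isoform per
    gene always remains annotated).
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    plans = _plan_genes(config, rng)
    genome_len = (plans[-1].origin + plans[-1].span + config.intergenic_gap
                  if plans else 2 * config.intergenic_gap)
    seq = _BASES[rng.integers(0, 4, size=genome_len)]

    all_transcripts: List[TranscriptModel] = []
    expression: Dict[str, Tuple[float, float]] = {}
    pas_done = set()
    for plan in plans:
        for t, xc, xt in zip(plan.transcripts, plan.x_ctrl, plan.x_treat):
            all_transcripts.append(t)
            expression[t.transcript_id] = (xc, xt)
            key = (t.strand, t.pas)
            if key not in pas_done:
                _plant_pas_context(seq, t.pas, t.strand, rng)
                pas_done.add(key)

    genome = GenomeSequence({CHROM: seq.tobytes().decode()})
    isoforms = Annotation(all_transcripts)

    # withhold novel isoforms from the reference
    eligible = [
        t.transcript_id
        for t in all_transcripts
        if len(isoforms.genes[t.gene_id]) > 1
    ]
    n_novel = int(round(config.fraction_novel_isoforms * len(all_transcripts)))
    novel: set = set()
    order = list(rng.permutation(np.array(sorted(eligible))))
    remaining_per_gene = {g: len(tids) for g, tids in isoforms.genes.items()}
    for tid in order:
        if len(novel) >= n_novel:
            break
        gid = isoforms.transcripts[str(tid)].gene_id
        if remaining_per_gene[gid] > 1:
            novel.add(str(tid))
            remaining_per_gene[gid] -= 1
    reference = Annotation(
        [t for t in all_transcripts if t.transcript_id not in novel]
    )

    manifest = TruthManifest(conditions=config.conditions)
    nulls: Dict[str, List[str]] = {
        "abundance": [], "promoter": [], "splicing": [], "apa": [],
    }
    for plan in plans:
        tids = [t.transcript_id for t in plan.transcripts]
        if plan.kind == "abund":
            for t, xc, xt in zip(plan.transcripts, plan.x_ctrl, plan.x_treat):
                manifest.effects.append({
                    "id": t.transcript_id,
                    "type": "abundance_shift",
                    "gene_id": plan.gene_id,
                    "params": {"ctrl": xc, "treat": xt},
                })
        elif plan.kind == "abundnull":
            nulls["abundance"].append(plan.gene_id)
        elif plan.kind == "apsw":
            manifest.effects.append({
                "id": plan.gene_id,
                "type": "ap_switch",
                "gene_id": plan.gene_id,
                "params": {
                    "promoter_members": [[tids[0]], [tids[1]]],
                    "ctrl": list(plan.x_ctrl),
                    "treat": list(plan.x_treat),
                },
            })
        elif plan.kind == "apnull":
            nulls["promoter"].append(plan.gene_id)
        elif plan.kind == "asshift":
            manifest.effects.append({
                "id": plan.gene_id,
                "type": "as_shift",
                "gene_id": plan.gene_id,
                "params": {
                    "event_type": plan.template,
                    "inclusion": [tids[0]],
                    "exclusion": [tids[1]],
                    "ctrl": plan.x_ctrl[0],
                    "treat": plan.x_treat[0],
                },
            })
        elif plan.kind == "asnull":
            nulls["splicing"].append(plan.gene_id)
        elif plan.kind == "apashift":
            manifest.effects.append({
                "id": plan.gene_id,
                "type": "apa_shift",
                "gene_id": plan.gene_id,
                "params": {
                    "distal": tids[0],
                    "proximal": tids[1],
                    "ctrl": plan.x_ctrl[0],
                    "treat": plan.x_treat[0],
                },
            })
        elif plan.kind == "apanull":
            nulls["apa"].append(plan.gene_id)
    manifest.nulls = nulls

    return SyntheticModels(
        genome=genome,
        reference=reference,
        isoforms=isoforms,
        expression=expression,
        manifest=manifest,
        config=config,
    )


@dataclass
class MeasurementBundle:
    flnc_counts: pd.DataFrame
    junction_counts: pd.DataFrame
    tpm: pd.DataFrame
    coverage: Dict[str, CoverageTrack]
    cage: List[BedRecord]
    pas_evidence: List[BedRecord]
    gene_expression: pd.DataFrame
    samples: Dict[str, List[str]]


def simulate_measurements(
    models: SyntheticModels,
    config: Optional[ScenarioConfig] = None,
    seed: Optional[int] = None,
) -> MeasurementBundle:
    """Sample every measurement type from the planted expression model."""
    config = config or models.config
    rng = np.random.default_rng(config.seed if seed is None else seed)
    cond_ctrl, cond_treat = config.conditions
    isoforms = models.isoforms
    tids = sorted(isoforms.transcripts)
    n_genes = len(isoforms.genes)
    x = {
        cond_ctrl: np.array([models.expression[t][0] for t in tids]),
        cond_treat: np.array([models.expression[t][1] for t in tids]),
    }

    # FLNC: one multinomial per condition over all isoforms
    flnc_rows = []
    total_flnc = config.flnc_depth_per_gene * n_genes
    for cond in config.conditions:
        probs = x[cond] / x[cond].sum()
        counts = rng.multinomial(total_flnc, probs)
        for tid, c in zip(tids, counts):
            flnc_rows.append(
                (tid, isoforms.transcripts[tid].gene_id, cond, int(c))
            )
    flnc_counts = pd.DataFrame(
        flnc_rows, columns=["transcript_id", "gene_id", "sample", "count"]
    )

    # junction counts: Poisson per sample around expression-weighted depth
    junction_transcripts: Dict[Tuple, List[str]] = {}
    for tid in tids:
        t = isoforms.transcripts[tid]
        for intron in t.introns:
            junction_transcripts.setdefault(
                (t.chrom, intron[0], intron[1], t.strand), []
            ).append(tid)
    junction_rows = []
    for (chrom, s, e, strand), members in sorted(junction_transcripts.items()):
        for cond in config.conditions:
            weight = sum(
                models.expression[m][0 if cond == cond_ctrl else 1] for m in members
            )
            lam = config.junction_depth_per_gene * weight / config.n_replicates
            for sample in config.samples[cond]:
                c = int(rng.poisson(lam))
                if c > 0:
                    junction_rows.append((chrom, s, e, strand, c, sample))
    junction_counts = pd.DataFrame(
        junction_rows, columns=["chrom", "start", "end", "strand", "count", "sample"]
    )

    # TPM replicates with mean-one lognormal noise
    sd = config.tpm_noise_sd
    tpm_cols = {}
    for cond in config.conditions:
        true_tpm = x[cond] / x[cond].sum() * 1e6
        for sample in config.samples[cond]:
            if sd > 0:
                noise = np.exp(rng.normal(0.0, sd, size=len(tids)) - sd * sd / 2.0)
            else:
                noise = np.ones(len(tids))
            tpm_cols[sample] = true_tpm * noise
    tpm = pd.DataFrame(tpm_cols, index=pd.Index(tids, name="transcript_id"))

    # coverage: uniform along each transcript, Poisson per base
    genome_len = models.genome.lengths[CHROM]
    coverage = {}
    for cond in config.conditions:
        lam = np.zeros(genome_len)
        for tid in tids:
            t = isoforms.transcripts[tid]
            w = config.coverage_depth * models.expression[tid][
                0 if cond == cond_ctrl else 1
            ]
            for (s, e) in t.exons:
                lam[s:e] += w
        depth = rng.poisson(lam).astype(np.float64)
        coverage[cond] = CoverageTrack.from_array(CHROM, depth)

    # 5' evidence: one jittered peak per distinct true TSS
    def jitter(pos: int) -> int:
        if config.jitter_sd > 0:
            pos = pos + int(round(rng.normal(0.0, config.jitter_sd)))
        return min(max(pos, 0), genome_len - 1)

    cage = []
    for (chrom, strand), arr in sorted(isoforms.tss_positions().items()):
        for i, p in enumerate(arr, start=1):
            q = jitter(int(p))
            cage.append(BedRecord(chrom, q, q + 1, f"cage_{strand}_{i}", 1, strand))

    # 3' evidence: jittered true PAS with >= min_pas_reads reads, plus decoys
    pas_evidence = []
    true_pas: Dict[str, List[int]] = {"+": [], "-": []}
    for (chrom, strand), arr in sorted(isoforms.pas_positions().items()):
        true_pas[strand].extend(int(p) for p in arr)
        for i, p in enumerate(arr, start=1):
            q = jitter(int(p))
            support = config.min_pas_reads + int(rng.poisson(15))
            pas_evidence.append(
                BedRecord(chrom, q, q + 1, f"pas_{strand}_{i}", support, strand)
            )
    n_decoys = 0
    guard = 0
    while n_decoys < config.n_decoy_pas and guard < 100 * (config.n_decoy_pas + 1):
        guard += 1
        pos = int(rng.integers(60, genome_len - 60))
        strand = "+" if rng.random() < 0.5 else "-"
        if any(abs(pos - p) < config.decoy_min_distance for p in true_pas[strand]):
            continue
        support = int(rng.integers(1, config.min_pas_reads))  # always < threshold
        n_decoys += 1
        pas_evidence.append(
            BedRecord(CHROM, pos, pos + 1, f"decoy_{n_decoys}", support, strand)
        )

    gene_expression = pd.DataFrame(
        {
            cond: [
                config.gene_fpkm
                * sum(
                    models.expression[t][0 if cond == cond_ctrl else 1]
                    for t in isoforms.genes[g]
                )
                for g in sorted(isoforms.genes)
            ]
            for cond in config.conditions
        },
        index=pd.Index(sorted(isoforms.genes), name="gene_id"),
    )

    return MeasurementBundle(
        flnc_counts=flnc_counts,
        junction_counts=junction_counts,
        tpm=tpm,
        coverage=coverage,
        cage=cage,
        pas_evidence=pas_evidence,
        gene_expression=gene_expression,
        samples=config.samples,
    )


def simulate_flnc_models(
    models: SyntheticModels,
    flnc_counts: pd.DataFrame,
    seed: Optional[int] = None,
    max_reads_per_transcript: Optional[int] = None,
) -> Dict[str, List[TranscriptModel]]:
    """Expand FLNC counts into per-read exon-chain models with jittered ends."""
    config = models.config
    rng = np.random.default_rng(config.seed if seed is None else seed)
    reads: Dict[str, List[TranscriptModel]] = {c: [] for c in config.conditions}
    for row in flnc_counts.itertuples(index=False):
        t = models.isoforms.transcripts[row.transcript_id]
        n = int(row.count)
        if max_reads_per_transcript is not None:
            n = min(n, max_reads_per_transcript)
        for i in range(n):
            d5 = int(round(rng.normal(0.0, config.jitter_sd))) if config.jitter_sd else 0
            d3 = int(round(rng.normal(0.0, config.jitter_sd))) if config.jitter_sd else 0
            # d5 moves the TSS-side genomic end, d3 the PAS side
            left_shift, right_shift = (d5, d3) if t.strand == "+" else (d3, d5)
            exons = list(t.exons)
            new_left = min(max(exons[0][0] + left_shift, 0), exons[0][1] - 1)
            new_right = max(exons[-1][1] + right_shift, exons[-1][0] + 1)
            exons[0] = (new_left, exons[0][1])
            exons[-1] = (exons[-1][0], new_right)
            if len(exons) == 1:
                exons[0] = (new_left, max(new_right, new_left + 1))
            reads[row.sample].append(
                TranscriptModel(
                    transcript_id=f"read_{row.sample}_{row.transcript_id}_{i}",
                    gene_id=t.gene_id,
                    chrom=t.chrom,
                    strand=t.strand,
                    exons=tuple(exons),
                )
            )
    return reads


def emit_scenario(
    models: SyntheticModels,
    bundle: MeasurementBundle,
    outdir,
    force: bool = False,
) -> Dict[str, str]:
    """Write the complete scenario file tree; returns name -> path."""
    outdir = Path(outdir)
    if outdir.exists() and any(outdir.iterdir()) and not force:
        raise DataError(f"output directory {outdir} exists and is not empty")
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}

    def p(name: str) -> Path:
        paths[name] = str(outdir / name)
        return outdir / name

    write_genome(models.genome, p("genome.fa"))
    write_annotation(models.reference, p("reference.gtf"))
    write_annotation(models.isoforms, p("isoforms.gtf"))
    write_table(bundle.flnc_counts, p("flnc_counts.tsv"))
    write_table(bundle.junction_counts, p("junctions.tsv"))
    write_table(bundle.tpm.reset_index(), p("tpm.tsv"))
    for cond, track in bundle.coverage.items():
        write_coverage(track, p(f"coverage_{cond}.bedGraph"))
    write_intervals(bundle.cage, p("cage.bed"))
    write_intervals(bundle.pas_evidence, p("pas_evidence.bed"))
    write_table(bundle.gene_expression.reset_index(), p("gene_expression.tsv"))
    models.manifest.to_json(p("truth.json"))
    return paths
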