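"""Structural categories against a brute-force oracle; internal priming."""

import itertools

import numpy as np
import pytest

from conftest import make_transcript
from isodyn.classify import (
    classify_isoform,
    detect_internal_priming,
    summarize_structural_categories,
    StructuralCall,
)
from isodyn.models import Annotation, DataError, GenomeSequence, TranscriptModel, reverse_complement


# ---- an independent, maximally naive classification oracle ------------------

def oracle_classify(iso, reference, mono_end_window=50):
    ref_list = list(reference)

    def overlaps(t, s, e):
        return t.start < e and s < t.end

    same_genes = sorted({
        t.gene_id for t in ref_list
        if t.strand == iso.strand and t.chrom == iso.chrom
        and overlaps_gene(reference, t.gene_id, iso)
    })
    anti_genes = sorted({
        t.gene_id for t in ref_list
        if t.strand != iso.strand and t.chrom == iso.chrom
        and overlaps_gene(reference, t.gene_id, iso)
    })
    if not iso.is_multi_exon:
        for t in sorted(ref_list, key=lambda t: t.transcript_id):
            if (t.chrom, t.strand) == (iso.chrom, iso.strand) and not t.is_multi_exon:
                if t.gene_id in same_genes and \
                        abs(t.start - iso.start) <= mono_end_window and \
                        abs(t.end - iso.end) <= mono_end_window:
                    return "FSM"
        if same_genes:
            return "genic"
        return "antisense" if anti_genes else "intergenic"

    chain = iso.introns
    for t in ref_list:
        if (t.chrom, t.strand) == (iso.chrom, iso.strand) and t.introns == chain:
            return "FSM"
    for t in ref_list:
        if (t.chrom, t.strand) != (iso.chrom, iso.strand):
            continue
        m = t.introns
        for i in range(len(m)):
            for j in range(i + 1, len(m) + 1):
                if m[i:j] == chain and (j - i) < len(m):
                    return "ISM"
    if len(same_genes) >= 2:
        spans = {}
        for g in same_genes:
            ts = [t for t in ref_list if t.gene_id == g]
            spans[g] = (min(t.start for t in ts), max(t.end for t in ts))
        for a, b in itertools.combinations(same_genes, 2):
            (s1, e1), (s2, e2) = spans[a], spans[b]
            if e1 <= s2 or e2 <= s1:
                return "fusion"
    donors = set()
    acceptors = set()
    for t in ref_list:
        if (t.chrom, t.strand) != (iso.chrom, iso.strand):
            continue
        for (s, e) in t.introns:
            donors.add(s if t.strand == "+" else e)
            acceptors.add(e if t.strand == "+" else s)
    annotated = all(
        (s if iso.strand == "+" else e) in donors
        and (e if iso.strand == "+" else s) in acceptors
        for (s, e) in chain
    )
    if same_genes:
        return "NIC" if annotated else "NNC"
    return "antisense" if anti_genes else "intergenic"


def overlaps_gene(reference, gene_id, iso):
    ts = reference.gene_transcripts(gene_id)
    s = min(t.start for t in ts)
    e = max(t.end for t in ts)
    return iso.start < e and s < iso.end


class TestCascadeExamples:
    def test_fsm(self, toy_reference):
        iso = make_transcript("q", "x", [(90, 200), (300, 400), (500, 600), (700, 810)])
        call = classify_isoform(iso, toy_reference)
        assert call.category == "FSM" and call.matched_reference_id == "ref.A1"

    def test_ism_consecutive_suffix(self, toy_reference):
        iso = make_transcript("q", "x", [(420, 600), (700, 800)])
        # last junction of ref.A1's chain only -> consecutive sub-chain
        assert classify_isoform(iso, toy_reference).category == "ISM"

    def test_nic_new_combination(self, toy_reference):
        # donor 200 (A1) with acceptor 500 (A2's second junction target)
        iso = make_transcript("q", "x", [(100, 200), (500, 600), (630, 800)])
        call = classify_isoform(iso, toy_reference)
        assert call.category == "NNC"  # 630 is a novel donor
        iso2 = make_transcript("q2", "x", [(100, 200), (300, 400), (700, 800)])
        assert classify_isoform(iso2, toy_reference).category == "NIC"

    def test_nnc_shifted_donor(self, toy_reference):
        iso = make_transcript("q", "x", [(100, 210), (300, 400)])
        assert classify_isoform(iso, toy_reference).category == "NNC"

    def test_fusion_spans_two_genes(self, toy_reference):
        iso = make_transcript("q", "x", [(150, 200), (300, 400), (2000, 2100), (2300, 2350)])
        assert classify_isoform(iso, toy_reference).category == "fusion"

    def test_mono_exon_positional_categories(self, toy_reference):
        inside = make_transcript("q", "x", [(210, 290)])        # intron of geneA
        assert classify_isoform(inside, toy_reference).category == "genic"
        anti = make_transcript("q", "x", [(5100, 5200)])        # geneC is '-'
        assert classify_isoform(anti, toy_reference).category == "antisense"
        nowhere = make_transcript("q", "x", [(9000, 9100)])
        assert classify_isoform(nowhere, toy_reference).category == "intergenic"

    def test_mono_exon_fsm_within_window(self, toy_reference):
        iso = make_transcript("q", "x", [(5030, 5380)], strand="-")
        call = classify_isoform(iso, toy_reference)
        assert call.category == "FSM" and call.matched_reference_id == "ref.C1"


def random_toy_catalogs(n_catalogs=40, seed=7):
    """Enumerate randomized toy references (<= 8 transcripts) and query isoforms."""
    rng = np.random.default_rng(seed)
    boundaries = list(range(0, 2400, 100))
    catalogs = []
    for _ in range(n_catalogs):
        ref_models = []
        for g in range(rng.integers(1, 4)):
            strand = "+" if rng.random() < 0.5 else "-"
            base = int(rng.integers(0, 3)) * 3000
            for t in range(rng.integers(1, 4)):
                starts = sorted(rng.choice(boundaries, size=rng.integers(1, 5), replace=False))
                exons = [(base + s, base + s + int(rng.integers(40, 100))) for s in starts]
                exons = [iv for i, iv in enumerate(exons)
                         if i == 0 or iv[0] >= exons[i - 1][1]]
                try:
                    ref_models.append(TranscriptModel(
                        f"ref.g{g}.t{t}", f"gene{g}", "chr1", strand, tuple(exons)))
                except DataError:
                    continue
        if not ref_models:
            continue
        queries = []
        for q in range(6):
            src = ref_models[int(rng.integers(0, len(ref_models)))]
            mode = rng.integers(0, 4)
            exons = list(src.exons)
            if mode == 1 and len(exons) > 1:
                exons = exons[int(rng.integers(0, len(exons) - 1)):]
            elif mode == 2:
                s, e = exons[0]
                exons[0] = (max(0, s - int(rng.integers(0, 120))), e)
            elif mode == 3:
                shift = int(rng.integers(-200, 200))
                exons = [(max(0, s + shift), e + shift) for s, e in exons]
            try:
                queries.append(TranscriptModel(
                    f"q{q}", "query", "chr1",
                    src.strand if rng.random() < 0.8 else ("-" if src.strand == "+" else "+"),
                    tuple(exons)))
            except DataError:
                continue
        catalogs.append((Annotation(ref_models), queries))
    return catalogs


class TestOracleAgreement:
    def test_matches_bruteforce_on_randomized_catalogs(self):
        n = 0
        for reference, queries in random_toy_catalogs():
            for iso in queries:
                got = classify_isoform(iso, reference).category
                want = oracle_classify(iso, reference)
                assert got == want, (iso, got, want)
                n += 1
        assert n > 100  # the sweep actually exercised many isoforms

    def test_every_isoform_gets_exactly_one_category(self, default_scenario):
        _, models, _ = default_scenario
        from isodyn.classify import CATEGORIES
        for t in models.isoforms:
            call = classify_isoform(t, models.reference)
            assert call.category in CATEGORIES
            assert (call.matched_reference_id is not None) == (
                call.category in ("FSM", "ISM")
            )


class TestInternalPriming:
    def plus_iso(self):
        return make_transcript("t", "g", [(0, 100)])

    def test_six_a_run_fires(self):
        g = GenomeSequence({"chr1": "C" * 100 + "AAAAAAGCGCGCGCGCGCGC"})
        assert detect_internal_priming(self.plus_iso(), g) is True

    def test_fraction_boundary_is_strict(self):
        # 13/20 = 65% scattered -> flagged; 12/20 = 60% -> not flagged
        thirteen = "AAAAAC" + "AAAAAC" + "AAACCC" + "CC"  # 13 A, no 6-run
        assert thirteen.count("A") == 13 and "AAAAAA" not in thirteen
        g = GenomeSequence({"chr1": "C" * 100 + thirteen})
        assert detect_internal_priming(self.plus_iso(), g) is True
        twelve = "AAAAAC" + "AAAAAC" + "AACCCC" + "CC"
        assert twelve.count("A") == 12 and "AAAAAA" not in twelve
        g = GenomeSequence({"chr1": "C" * 100 + twelve})
        assert detect_internal_priming(self.plus_iso(), g) is False

    def test_minus_strand_reads_complemented_t(self):
        g = GenomeSequence({"chr1": "G" * 30 + "TTTTTT" + "G" * 64})
        iso = make_transcript("t", "g", [(36, 100)], strand="-")
        assert detect_internal_priming(iso, g) is True

    def test_strand_flip_invariance(self):
        """Flagging is invariant under mirroring to the reverse-complemented genome."""
        rng = np.random.default_rng(3)
        seq = "".join(rng.choice(list("ACGT"), size=400))
        g_fwd = GenomeSequence({"chr1": seq})
        g_rev = GenomeSequence({"chr1": reverse_complement(seq)})
        iso_fwd = make_transcript("t", "g", [(100, 200)], strand="+")
        iso_rev = make_transcript("t", "g", [(200, 300)], strand="-")
        assert detect_internal_priming(iso_fwd, g_fwd) == detect_internal_priming(iso_rev, g_rev)

    def test_truncated_window_at_edge(self):
        g = GenomeSequence({"chr1": "C" * 100 + "AAA"})
        assert detect_internal_priming(self.plus_iso(), g) is True  # 3/3 A > 60%


class TestSummary:
    def test_single_call(self):
        out = summarize_structural_categories([StructuralCall("t", "NIC")])
        assert out["NIC"] == {"count": 1, "percent": 100.0}

    def test_empty_rejected(self):
        with pytest.raises(DataError):
            summarize_structural_categories([])

    def test_category_filter_changes_denominator(self):
        calls = [StructuralCall("a", "FSM"), StructuralCall("b", "intergenic")]
        full = summarize_structural_categories(calls)
        sliced = summarize_structural_categories(calls, categories=["FSM"])
        assert full["FSM"]["percent"] == 50.0
        assert sliced["FSM"]["percent"] == 100.0
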