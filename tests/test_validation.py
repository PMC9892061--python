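"""Evidence pools, support windows, TSS deduplication, FLNC assignment."""

import math

import pandas as pd
import pytest

from conftest import make_transcript
from isodyn.io import BedRecord
from isodyn.models import Annotation, DataError
from isodyn.simulate import simulate_flnc_models
from isodyn.validation import (
    FlncAssignment,
    assign_flnc_reads,
    build_evidence_pools,
    deduplicate_by_tss,
    evaluate_support,
    summarize_support,
)


def junction_df(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "strand", "count", "sample"])


@pytest.fixture()
def mini_reference():
    return Annotation([
        make_transcript("r1", "g1", [(100, 200), (300, 400)]),
    ])


class TestPools:
    def test_pas_read_threshold_is_inclusive_at_five(self, mini_reference):
        pas = [
            BedRecord("chr1", 999, 1000, "weak", 4, "+"),
            BedRecord("chr1", 1999, 2000, "strong", 5, "+"),
        ]
        pools = build_evidence_pools([], pas, [], mini_reference)
        positions = set(int(p) for p in pools.pas[("chr1", "+")])
        assert 999 not in positions       # 4 reads: below the >=5 rule
        assert 1999 in positions          # exactly 5 reads: kept
        assert 400 in positions           # reference PAS always in the pool

    def test_reference_tss_present_without_cage(self, mini_reference):
        pools = build_evidence_pools([], [], [], mini_reference)
        assert 100 in set(int(p) for p in pools.tss[("chr1", "+")])

    def test_cage_midpoint_used(self, mini_reference):
        cage = [BedRecord("chr1", 500, 511, "peak", 0, "+")]
        pools = build_evidence_pools(cage, [], [], mini_reference)
        assert 505 in set(int(p) for p in pools.tss[("chr1", "+")])

    def test_junction_counts_summed_across_samples(self, mini_reference):
        tables = [junction_df([("chr1", 200, 300, "+", 3, "s1"),
                               ("chr1", 200, 300, "+", 4, "s2")])]
        pools = build_evidence_pools([], [], tables, mini_reference)
        assert pools.junctions[("chr1", 200, 300, "+")] == 7

    def test_empty_reference_rejected(self):
        with pytest.raises(DataError):
            build_evidence_pools([], [], [], Annotation([]))


class TestSupport:
    @pytest.mark.parametrize("pool_pos,supported,distance", [
        (1040, True, 40),
        (1050, True, 50),   # inclusive window boundary
        (1060, False, 60),
    ])
    def test_tss_window_inclusive(self, mini_reference, pool_pos, supported, distance):
        iso = make_transcript("t", "g1", [(1000, 1200), (1300, 1400)])
        cage = [BedRecord("chr1", pool_pos, pool_pos + 1, "p", 0, "+")]
        pools = build_evidence_pools(cage, [], [], mini_reference)
        report = evaluate_support(iso, pools)
        assert report.tss_supported is supported
        assert report.tss_distance == distance

    @pytest.mark.parametrize("count,ok", [(1, False), (2, True)])
    def test_junction_needs_two_reads(self, mini_reference, count, ok):
        iso = make_transcript("t", "g1", [(100, 200), (300, 400)])
        tables = [junction_df([("chr1", 200, 300, "+", count, "s1")])]
        pools = build_evidence_pools([], [], tables, mini_reference)
        (_, supported, n) = evaluate_support(iso, pools).junctions[0]
        assert supported is ok and n == count

    def test_absent_chromosome_gives_infinite_distance(self, mini_reference):
        iso = make_transcript("t", "g1", [(0, 100)], chrom="chrX")
        pools = build_evidence_pools([], [], [], mini_reference)
        report = evaluate_support(iso, pools)
        assert not report.tss_supported and math.isinf(report.tss_distance)

    def test_summarize_rates(self, mini_reference):
        pools = build_evidence_pools(
            [], [], [junction_df([("chr1", 200, 300, "+", 5, "s")])], mini_reference
        )
        reports = [
            evaluate_support(make_transcript("a", "g1", [(100, 200), (300, 400)]), pools),
            evaluate_support(make_transcript("b", "g1", [(100, 200), (310, 400)]), pools),
            evaluate_support(make_transcript("c", "g1", [(95, 200), (300, 405)]), pools),
        ]
        rates = summarize_support(reports)
        assert rates["tss_rate"] == pytest.approx(100.0)
        assert rates["junction_rate"] == pytest.approx(100.0 * 2 / 3)

    def test_summarize_empty_rejected(self):
        with pytest.raises(DataError):
            summarize_support([])

    def test_window_monotonicity(self, default_scenario):
        """Support rates never decrease with a wider window, never increase
        with a stricter junction-read floor."""
        _, models, bundle = default_scenario
        pools = build_evidence_pools(
            bundle.cage, bundle.pas_evidence, [bundle.junction_counts], models.reference
        )
        isoforms = list(models.isoforms)

        def rates(window, min_reads):
            return summarize_support([
                evaluate_support(t, pools, end_window=window,
                                 min_junction_reads=min_reads)
                for t in isoforms
            ])

        r10, r50 = rates(10, 2), rates(50, 2)
        assert r10["tss_rate"] <= r50["tss_rate"]
        assert r10["pas_rate"] <= r50["pas_rate"]
        strict = rates(50, 10 ** 6)
        assert strict["junction_rate"] <= r50["junction_rate"]


class TestDedup:
    def pools_with_tss(self, *positions):
        ref = Annotation([make_transcript("r", "g", [(10 ** 6, 10 ** 6 + 100)])])
        cage = [BedRecord("chr1", p, p + 1, "c", 0, "+") for p in positions]
        return build_evidence_pools(cage, [], [], ref)

    def test_keeps_closest_tss(self):
        pools = self.pools_with_tss(495)
        isos = [
            make_transcript("far", "g", [(450, 600), (700, 830)]),
            make_transcript("near", "g", [(500, 600), (700, 800)]),
        ]
        kept, dropped = deduplicate_by_tss(isos, pools)
        assert [t.transcript_id for t in kept] == ["near"]
        assert dropped == {"far": "near"}

    def test_distant_pas_not_grouped(self):
        pools = self.pools_with_tss(500)
        isos = [
            make_transcript("a", "g", [(500, 600), (700, 800)]),
            make_transcript("b", "g", [(500, 600), (700, 880)]),  # PAS 80 apart
        ]
        kept, dropped = deduplicate_by_tss(isos, pools)
        assert len(kept) == 2 and not dropped

    def test_tie_keeps_five_prime_most(self):
        pools = self.pools_with_tss(500)  # distances 10 and 10
        isos = [
            make_transcript("down", "g", [(510, 600), (700, 800)]),
            make_transcript("up", "g", [(490, 600), (700, 800)]),
        ]
        kept, _ = deduplicate_by_tss(isos, pools)
        assert [t.transcript_id for t in kept] == ["up"]

    def test_idempotent(self, default_scenario):
        _, models, bundle = default_scenario
        pools = build_evidence_pools(
            bundle.cage, bundle.pas_evidence, [bundle.junction_counts], models.reference
        )
        once, map1 = deduplicate_by_tss(list(models.isoforms), pools)
        twice, map2 = deduplicate_by_tss(once, pools)
        assert [t.transcript_id for t in once] == [t.transcript_id for t in twice]
        assert map2 == {}

    def test_no_group_mixes_chains_on_clean_data(self, default_scenario):
        _, models, bundle = default_scenario
        pools = build_evidence_pools(
            bundle.cage, bundle.pas_evidence, [bundle.junction_counts], models.reference
        )
        _, dropped = deduplicate_by_tss(list(models.isoforms), pools)
        for d, k in dropped.items():
            assert models.isoforms.transcripts[d].introns == \
                models.isoforms.transcripts[k].introns


class TestFlncAssignment:
    def catalog(self):
        return Annotation([
            make_transcript("iso1", "g", [(1000, 1200), (1400, 1600)]),
            make_transcript("iso2", "g", [(1045, 1200), (1400, 1600)]),
            make_transcript("mono", "g2", [(5000, 5500)]),
        ])

    def test_matching_chain_with_end_slack(self):
        reads = {"ctrl": [make_transcript("r", "g", [(990, 1200), (1400, 1620)])]}
        asn = assign_flnc_reads(reads, self.catalog())
        assert asn.count("iso1", "ctrl") == 1

    def test_extra_junction_unassigned(self):
        reads = {"ctrl": [make_transcript("r", "g", [(1000, 1100), (1150, 1200), (1400, 1600)])]}
        asn = assign_flnc_reads(reads, self.catalog())
        assert asn.unassigned["ctrl"] == 1

    def test_closest_end_wins_among_candidates(self):
        # identical chains, TSS distances 5 (iso1) vs 40 (iso2)
        reads = {"ctrl": [make_transcript("r", "g", [(1005, 1200), (1400, 1600)])]}
        asn = assign_flnc_reads(reads, self.catalog())
        assert asn.count("iso1", "ctrl") == 1
        assert asn.count("iso2", "ctrl") == 0

    def test_mono_exon_matches_mono_exon_only(self):
        reads = {"ctrl": [make_transcript("r", "g2", [(5010, 5490)])]}
        asn = assign_flnc_reads(reads, self.catalog())
        assert asn.count("mono", "ctrl") == 1

    def test_conservation_on_simulated_reads(self, default_scenario):
        """Assigned + unassigned reads equal input per condition, and the
        recovered counts match the planted multinomial draw."""
        config, models, bundle = default_scenario
        reads = simulate_flnc_models(models, bundle.flnc_counts, seed=9,
                                     max_reads_per_transcript=20)
        asn = assign_flnc_reads(reads, models.isoforms)
        for cond, read_list in reads.items():
            assigned = sum(
                n for (tid, c), n in asn.counts.items() if c == cond
            )
            assert assigned + asn.unassigned.get(cond, 0) == len(read_list)
            # jitter is small relative to the windows: nearly all assign back
            assert asn.unassigned.get(cond, 0) <= 0.01 * len(read_list)

    def test_count_table_round_trip(self, default_scenario):
        _, _, bundle = default_scenario
        asn = FlncAssignment.from_count_table(bundle.flnc_counts)
        totals = bundle.flnc_counts.groupby("sample")["count"].sum()
        for cond, total in totals.items():
            assert asn.totals[cond] == total
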