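"""PAS clustering, sequence context, APA regions, PDUI and differential calls."""

import itertools
import math

import numpy as np
import pytest

from conftest import make_transcript
from isodyn.apa import (
    build_apa_regions,
    cluster_pas_sites,
    label_pas_clusters,
    pas_nucleotide_profile,
    quantify_pdui,
    scan_polya_signal,
    test_differential_apa as differential_apa,
    ApaRegion,
)
from isodyn.models import Annotation, CoverageTrack, GenomeSequence


def oracle_single_linkage(positions, window=50):
    """Brute-force clustering: connected components of the <=window graph."""
    positions = sorted(positions)
    parent = list(range(len(positions)))

    def find(i):
        while parent[i] != i:
            i = parent[i]
        return i

    for i, j in itertools.combinations(range(len(positions)), 2):
        if abs(positions[i] - positions[j]) <= window:
            parent[find(i)] = find(j)
    groups = {}
    for i, p in enumerate(positions):
        groups.setdefault(find(i), []).append(p)
    return sorted(tuple(sorted(g)) for g in groups.values())


class TestClustering:
    def test_chain_rule(self):
        clusters = cluster_pas_sites({("chr1", "+"): [(100, 1), (130, 1), (190, 1)]})
        members = sorted(c.members for c in clusters)
        assert members == [(100, 130), (190,)]  # 130->190 gap is 60 > 50

    def test_representative_max_support(self):
        (c,) = cluster_pas_sites({("chr1", "+"): [(100, 3), (130, 7)]})
        assert c.representative == 130 and c.support == 10

    def test_representative_tie_five_prime_most(self):
        (plus,) = cluster_pas_sites({("chr1", "+"): [(100, 5), (130, 5)]})
        (minus,) = cluster_pas_sites({("chr1", "-"): [(100, 5), (130, 5)]})
        assert plus.representative == 100
        assert minus.representative == 130

    def test_singleton(self):
        (c,) = cluster_pas_sites({("chr1", "+"): [(42, 9)]})
        assert c.representative == 42 and c.members == (42,)

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            positions = sorted(set(rng.integers(0, 1000, size=rng.integers(1, 10))))
            supports = [(int(p), 1) for p in positions]
            clusters = cluster_pas_sites({("chr1", "+"): supports})
            got = sorted(c.members for c in clusters)
            assert got == oracle_single_linkage(positions)

    def test_consecutive_clusters_separated(self, default_scenario):
        _, models, _ = default_scenario
        pas = {}
        for t in models.isoforms:
            pas.setdefault((t.chrom, t.strand), []).append((t.pas, 1))
        clusters = cluster_pas_sites(pas)
        by_key = {}
        for c in clusters:
            by_key.setdefault((c.chrom, c.strand), []).append(c)
        for group in by_key.values():
            group.sort(key=lambda c: c.representative)
            for a, b in zip(group, group[1:]):
                assert min(b.members) - max(a.members) > 50


class TestKnownLabels:
    def reference(self):
        return Annotation([make_transcript("r", "g", [(800, 1000)])])  # PAS 1000

    @pytest.mark.parametrize("rep,known", [(1049, True), (1051, False)])
    def test_distance_boundary(self, rep, known):
        (c,) = cluster_pas_sites({("chr1", "+"): [(rep, 1)]})
        (c,) = label_pas_clusters([c], self.reference())
        assert c.known is known

    def test_opposite_strand_is_novel(self):
        (c,) = cluster_pas_sites({("chr1", "-"): [(1000, 1)]})
        (c,) = label_pas_clusters([c], self.reference())
        assert c.known is False


class TestSequenceContext:
    def test_planted_profile_and_signal(self, default_scenario):
        """The generator plants AATAAA at -20 and an A-rich -25..-1 window."""
        _, models, _ = default_scenario
        pas = {}
        for t in models.isoforms:
            pas.setdefault((t.chrom, t.strand), []).append((t.pas, 1))
        clusters = cluster_pas_sites(pas)
        profile = pas_nucleotide_profile(clusters, models.genome)
        upstream_a = profile.loc[-25:-1, "A"].mean()
        background_a = profile.loc[5:, "A"].mean()
        assert upstream_a > 0.4
        assert abs(background_a - 0.25) < 0.15
        assert scan_polya_signal(clusters, models.genome) == 1.0

    def test_strand_symmetry(self):
        rng = np.random.default_rng(5)
        seq = "".join(rng.choice(list("ACGT"), size=200))
        from isodyn.models import reverse_complement
        g_fwd = GenomeSequence({"chr1": seq})
        g_rev = GenomeSequence({"chr1": reverse_complement(seq)})
        (c_fwd,) = cluster_pas_sites({("chr1", "+"): [(100, 1)]})
        (c_rev,) = cluster_pas_sites({("chr1", "-"): [(100, 1)]})
        p_fwd = pas_nucleotide_profile([c_fwd], g_fwd)
        p_rev = pas_nucleotide_profile([c_rev], g_rev)
        assert np.allclose(p_fwd.values, p_rev.values)


class TestRegions:
    def catalog(self, pas_positions, strand="+"):
        models = []
        for i, p in enumerate(pas_positions):
            if strand == "+":
                exons = [(800, 900), (1000, p)]
            else:
                exons = [(p, 2000), (2200, 2300)]
            models.append(make_transcript(f"t{i}", "g", exons, strand=strand))
        return Annotation(models)

    def clusters(self, positions, strand="+"):
        return cluster_pas_sites({("chr1", strand): [(p, 1) for p in positions]})

    def test_two_pas_regions(self):
        ann = self.catalog([1400, 1900])
        (region,) = build_apa_regions(ann, self.clusters([1400, 1900]))
        assert region.common == (1000, 1400)
        assert region.extended == (1400, 1900)

    def test_single_pas_gene_excluded(self):
        ann = self.catalog([1900])
        assert build_apa_regions(ann, self.clusters([1900])) == []

    def test_three_pas_uses_outermost(self):
        ann = self.catalog([1200, 1500, 1900])
        (region,) = build_apa_regions(ann, self.clusters([1200, 1500, 1900]))
        assert (region.proximal, region.distal) == (1200, 1900)

    def test_minus_strand_orientation(self):
        ann = self.catalog([1000, 1500], strand="-")
        (region,) = build_apa_regions(ann, self.clusters([1000, 1500], strand="-"))
        assert (region.proximal, region.distal) == (1500, 1000)
        assert region.common == (1500, 2000)
        assert region.extended == (1000, 1500)


def uniform_track(common_depth, extended_depth):
    return CoverageTrack.from_intervals([
        ("chr1", 1000, 1400, common_depth),
        ("chr1", 1400, 1900, extended_depth),
    ])


REGION = ApaRegion("g", "chr1", "+", common=(1000, 1400), extended=(1400, 1900),
                   proximal=1400, distal=1900)


class TestPdui:
    def test_ratio(self):
        assert quantify_pdui(REGION, uniform_track(20, 5)) == pytest.approx(0.25)

    def test_zero_extended_full_shortening(self):
        assert quantify_pdui(REGION, uniform_track(20, 0)) == 0.0

    def test_equal_depth_distal_only(self):
        assert quantify_pdui(REGION, uniform_track(20, 20)) == 1.0

    def test_zero_common_is_na(self):
        assert math.isnan(quantify_pdui(REGION, uniform_track(0, 0)))

    def test_mixture_identity(self):
        """PDUI recovers the distal weight of a two-isoform mixture."""
        for w in (0.0, 0.2, 0.5, 0.9, 1.0):
            track = uniform_track(100.0, 100.0 * w)
            assert quantify_pdui(REGION, track) == pytest.approx(w)

    def test_monotone_in_extended_depth(self):
        values = [quantify_pdui(REGION, uniform_track(50, d)) for d in (0, 10, 25, 50)]
        assert values == sorted(values)


class TestDifferentialApa:
    def test_identical_coverage_unchanged(self):
        track = uniform_track(50, 40)
        (rec,) = differential_apa([REGION], track, track)
        assert rec.p_value == pytest.approx(1.0)
        assert rec.call == "unchanged"

    def test_strong_shortening_called(self):
        (rec,) = differential_apa(
            [REGION], uniform_track(50, 40), uniform_track(50, 15)
        )
        assert rec.delta_pdui == pytest.approx(-0.5)
        assert rec.call == "shortened"

    def test_delta_gate_blocks_small_shift(self):
        # |delta| = 0.15 with large depths: p is tiny but the gate fails
        (rec,) = differential_apa(
            [REGION], uniform_track(5000, 4000), uniform_track(5000, 3250)
        )
        assert rec.adjusted_p < 0.05
        assert rec.call == "unchanged"

    def test_strand_mirror_symmetry(self, default_scenario):
        """Mirroring the scenario's coordinates leaves PDUI unchanged."""
        _, models, bundle = default_scenario
        pas = {}
        for t in models.isoforms:
            pas.setdefault((t.chrom, t.strand), []).append((t.pas, 1))
        regions = build_apa_regions(models.isoforms, cluster_pas_sites(pas))
        genome_len = models.genome.lengths["chr1"]
        cov = bundle.coverage["control"]
        mirrored = CoverageTrack.from_intervals(sorted(
            ("chr1", genome_len - e, genome_len - s, d)
            for (s, e, d) in cov.intervals("chr1")
        ))
        for region in regions:
            flipped = ApaRegion(
                region.gene_id, "chr1",
                "-" if region.strand == "+" else "+",
                common=(genome_len - region.common[1], genome_len - region.common[0]),
                extended=(genome_len - region.extended[1], genome_len - region.extended[0]),
                proximal=genome_len - region.proximal,
                distal=genome_len - region.distal,
            )
            direct = quantify_pdui(region, cov)
            mirror = quantify_pdui(flipped, mirrored)
            assert mirror == pytest.approx(direct, abs=1e-9)
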