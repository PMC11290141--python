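"""CRE classification: location, K4 split, A/R/M/U labels, target genes,
homoeologous matching."""

import numpy as np
import pandas as pd
import pytest

from verncre.cre import (
    MarkRegions, annotate_acrs, assign_target_gene, classify_location,
    dacr_gene_distance_shift, label_modification, local_alignment,
    match_homoeologous_dacrs, split_by_k4,
)
from verncre.intervals import GeneModel, Interval, IntervalIndex


def gene(gid, chrom, start, end, strand="+", triad=None):
    return GeneModel(gid, Interval(chrom, start, end, name=gid, strand=strand),
                     triad)


class TestLocation:
    @pytest.fixture()
    def gene_index(self):
        return IntervalIndex([Interval("c", 10_000, 12_000)])

    def test_within_2kb_is_promoter(self, gene_index):
        assert classify_location(Interval("c", 8_100, 8_500), gene_index) == "promoter"

    def test_overlapping_gene_is_promoter(self, gene_index):
        assert classify_location(Interval("c", 11_000, 11_400), gene_index) == "promoter"

    def test_boundary_2000_promoter_2001_distal(self, gene_index):
        assert classify_location(Interval("c", 7_600, 8_000), gene_index) == "promoter"
        assert classify_location(Interval("c", 7_599, 7_999), gene_index) == "distal"


class TestK4Split:
    def test_peak_within_flank(self):
        k4 = IntervalIndex([Interval("c", 5_700, 6_000)])
        # peak 300 bp from the ACR edge, flank 500 -> K4-dACR
        assert split_by_k4(Interval("c", 5_000, 5_400), k4) == "K4-dACR"

    def test_peak_far_away(self):
        k4 = IntervalIndex([Interval("c", 10_400, 10_600)])
        assert split_by_k4(Interval("c", 5_000, 5_400), k4) == "nK4-dACR"

    def test_zero_flank_is_direct_overlap(self):
        k4 = IntervalIndex([Interval("c", 5_400, 5_600)])
        assert split_by_k4(Interval("c", 5_000, 5_400), k4, flank=0) == "nK4-dACR"
        assert split_by_k4(Interval("c", 5_000, 5_401), k4, flank=0) == "K4-dACR"

    def test_missing_k4_defaults_nk4(self):
        assert split_by_k4(Interval("c", 0, 100), None) == "nK4-dACR"


class TestModificationLabel:
    def _indexes(self, ac=(), me=(), k4=()):
        return (IntervalIndex([Interval("c", *s) for s in ac]),
                IntervalIndex([Interval("c", *s) for s in me]),
                IntervalIndex([Interval("c", *s) for s in k4]))

    def test_k27ac_only_is_activated(self):
        ac, me, _ = self._indexes(ac=[(5_500, 6_000)])
        assert label_modification(Interval("c", 5_000, 5_400), ac, me) == "A"

    def test_both_marks_is_mixed(self):
        ac, me, _ = self._indexes(ac=[(5_500, 6_000)], me=[(4_000, 4_600)])
        assert label_modification(Interval("c", 5_000, 5_400), ac, me) == "M"

    def test_k27me3_only_is_repressed(self):
        ac, me, _ = self._indexes(me=[(4_000, 4_600)])
        assert label_modification(Interval("c", 5_000, 5_400), ac, me) == "R"

    def test_nothing_near_is_unmodified(self):
        ac, me, _ = self._indexes()
        assert label_modification(Interval("c", 5_000, 5_400), ac, me) == "U"

    def test_k4_nearby_blocks_unmodified(self):
        # no K27 mark but H3K4me3 within flank: not U (reported A)
        ac, me, k4 = self._indexes(k4=[(5_500, 6_000)])
        got = label_modification(Interval("c", 5_000, 5_400), ac, me, k4_index=k4)
        assert got == "A"
        got2 = label_modification(Interval("c", 5_000, 5_400), ac, me,
                                  k4_index=k4, k4_counts_as_active=False)
        assert got2 == "U"


class TestTargetAssignment:
    def test_upstream_distance_negative(self):
        g = gene("g1", "c", 40_000, 42_000)
        tid, d = assign_target_gene(Interval("c", 9_900, 10_100), [g])
        assert tid == "g1" and d == -(40_000 - 10_099)

    def test_tie_breaks_lexicographically(self):
        ga = gene("gA", "c", 20_000, 21_000)          # TSS 20,000
        gb = gene("gB", "c", 9_000, 10_000, "-")      # TSS 10,000
        acr = Interval("c", 14_950, 15_051)           # midpoint equidistant
        # distances: to gA TSS = 20,000-15,050 = 4,950; to gB = 14,950-10,000 = 4,950
        tid, d = assign_target_gene(acr, [ga, gb])
        assert tid == "gA"

    def test_tss_inside_acr_distance_zero(self):
        g = gene("g1", "c", 10_000, 12_000)
        tid, d = assign_target_gene(Interval("c", 9_900, 10_100), [g])
        assert (tid, d) == ("g1", 0)

    def test_no_genes_on_chromosome(self):
        g = gene("g1", "other", 0, 1000)
        assert assign_target_gene(Interval("c", 0, 100), [g]) == (None, None)

    def test_matches_brute_force_scan(self):
        rng = np.random.default_rng(0)
        genes = []
        for i in range(120):
            s = int(rng.integers(0, 490_000))
            genes.append(gene(f"g{i:03d}", "c", s, s + 1000,
                              "+" if rng.random() < 0.5 else "-"))
        for _ in range(300):
            s = int(rng.integers(0, 499_000))
            acr = Interval("c", s, s + int(rng.integers(100, 800)))
            tid, d = assign_target_gene(acr, genes)
            # brute force: minimal distance then lexicographic id
            def dist(g):
                if acr.start <= g.tss < acr.end:
                    return 0
                return min(abs(g.tss - acr.start), abs(g.tss - (acr.end - 1)))
            best = min(genes, key=lambda g: (dist(g), g.gene_id))
            assert tid == best.gene_id
            assert abs(d) == dist(best)


class TestAlignmentAndHomology:
    def brute_sw(self, s1, s2, match=2, mismatch=-2, gap=-3):
        n, m = len(s1), len(s2)
        H = np.zeros((n + 1, m + 1))
        best = 0.0
        for i in range(1, n + 1):
            for j in range(1, m + 1):
                sub = match if s1[i - 1] == s2[j - 1] else mismatch
                H[i, j] = max(0, H[i - 1, j - 1] + sub,
                              H[i - 1, j] + gap, H[i, j - 1] + gap)
                best = max(best, H[i, j])
        return best

    def test_score_matches_quadratic_dp(self):
        rng = np.random.default_rng(0)
        bases = np.array(list("ACGT"))
        for _ in range(15):
            s1 = "".join(rng.choice(bases, int(rng.integers(20, 120))))
            s2 = "".join(rng.choice(bases, int(rng.integers(20, 120))))
            score, _, _ = local_alignment(s1, s2)
            assert score == pytest.approx(self.brute_sw(s1, s2))

    def test_identical_planted_sequences_syntenic(self):
        rng = np.random.default_rng(1)
        core = "".join(rng.choice(list("ACGT"), 200))
        seqs = {"chr1A": "T" * 500 + core + "T" * 500,
                "chr1B": "G" * 500 + core + "G" * 500,
                "chr1D": "C" * 1200}
        dacrs = pd.DataFrame([
            dict(acr_id="e1", chrom="chr1A", start=500, end=700, target_gene="gA"),
            dict(acr_id="e2", chrom="chr1B", start=500, end=700, target_gene="gB"),
            dict(acr_id="e3", chrom="chr1D", start=500, end=700, target_gene="gD"),
        ])
        triad_of = {"gA": "t1", "gB": "t1", "gD": "t1"}
        status = match_homoeologous_dacrs(dacrs, seqs, triad_of)
        assert status["e1"] == "syntenic(A:B)"
        assert status["e2"] == "syntenic(A:B)"
        assert status["e3"] == "specific"

    def test_target_mismatch_blocks_homology(self):
        rng = np.random.default_rng(2)
        core = "".join(rng.choice(list("ACGT"), 200))
        seqs = {"chr1A": core, "chr1B": core}
        dacrs = pd.DataFrame([
            dict(acr_id="e1", chrom="chr1A", start=0, end=200, target_gene="gA"),
            dict(acr_id="e2", chrom="chr1B", start=0, end=200, target_gene="gX"),
        ])
        status = match_homoeologous_dacrs(dacrs, seqs, {"gA": "t1", "gX": "t9"})
        assert (status == "specific").all()

    def test_homology_symmetric_and_order_invariant(self):
        rng = np.random.default_rng(3)
        core = "".join(rng.choice(list("ACGT"), 150))
        seqs = {"chr1A": core + "A" * 50, "chr1B": core + "C" * 50}
        rows = [
            dict(acr_id="e1", chrom="chr1A", start=0, end=150, target_gene="gA"),
            dict(acr_id="e2", chrom="chr1B", start=0, end=150, target_gene="gB"),
        ]
        triad_of = {"gA": "t1", "gB": "t1"}
        s1 = match_homoeologous_dacrs(pd.DataFrame(rows), seqs, triad_of)
        s2 = match_homoeologous_dacrs(pd.DataFrame(rows[::-1]), seqs, triad_of)
        assert s1.to_dict() == s2.to_dict()


class TestDistanceShift:
    def test_table_contents(self):
        pairs = pd.DataFrame([
            dict(pair_id="p1", distance_1=-2_500, distance_2=25_000),
            dict(pair_id="p2", distance_1=-1_500, distance_2=1_500),
        ])
        out = dacr_gene_distance_shift(pairs)
        assert len(out) == 2
        assert out.loc[0, "shift"] == 22_500
        assert not out.loc[0, "promoter_origin_1"] and not out.loc[0, "promoter_origin_2"]
        assert out.loc[1, "shift"] == 0
        assert out.loc[1, "promoter_origin_1"] and out.loc[1, "promoter_origin_2"]


class TestAnnotatePartition:
    def test_every_acr_gets_one_class_and_label(self, tiny_genome):
        truth = tiny_genome.truth
        from verncre.synthetic import simulate_mark_tracks
        marks = simulate_mark_tracks(tiny_genome, truth, "before")
        regions = MarkRegions(
            k4me3=marks["H3K4me3"][1], k27ac=marks["H3K27ac"][1],
            k27me3=marks["H3K27me3"][1], k36me3=marks["H3K36me3"][1],
        )
        acrs = truth.acr_intervals()
        ann = annotate_acrs(acrs, tiny_genome.genes, regions)
        assert len(ann) == len(acrs)
        assert set(ann.cre_class) <= {"promoter", "K4-dACR", "nK4-dACR"}
        assert set(ann.mod_label) <= {"A", "R", "M", "U"}
        # planted class recovered with >= 98% agreement on truth positions
        agree = (ann.set_index("acr_id").cre_class
                 == truth.acrs.set_index("acr_id").cre_class).mean()
        assert agree >= 0.98

    def test_order_invariance(self, tiny_genome):
        truth = tiny_genome.truth
        from verncre.synthetic import simulate_mark_tracks
        marks = simulate_mark_tracks(tiny_genome, truth, "before")
        regions = MarkRegions(
            k4me3=marks["H3K4me3"][1], k27ac=marks["H3K27ac"][1],
            k27me3=marks["H3K27me3"][1],
        )
        acrs = truth.acr_intervals()
        a1 = annotate_acrs(acrs, tiny_genome.genes, regions).set_index("acr_id")
        a2 = annotate_acrs(acrs[::-1], tiny_genome.genes, regions).set_index("acr_id")
        pd.testing.assert_frame_equal(a1.sort_index(), a2.sort_index())
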