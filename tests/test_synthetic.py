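"""Ground-truth contracts of the synthetic hexaploid generator."""

import numpy as np
import pytest

from verncre.genomio import read_bed, read_bedgraph, read_fasta, read_gff3
from verncre.intervals import Interval, IntervalIndex
from verncre.synthetic import (
    ConfigError, GroundTruth, SyntheticConfig, generate_genome,
    plant_auxiliary_features, simulate_expression, simulate_mark_tracks,
    simulate_tis_track, SPL_CONSENSUS,
)


class TestGenerateGenome:
    def test_triad_and_gene_counts(self, tiny_genome, tiny_config):
        assert len(tiny_genome.truth.triads) == tiny_config.n_triads
        expected = tiny_config.n_triads * 3 + tiny_config.n_singletons
        assert len(tiny_genome.genes) == expected

    def test_default_counts_forced_by_config(self):
        cfg = SyntheticConfig(seed=0)
        cfg.validate()
        assert cfg.n_triads == 300 and cfg.n_singletons == 60
        # 300 triads x 3 + 60 singletons = 960 genes; checked on the tiny
        # genome above at scaled-down counts

    def test_deterministic_outputs(self, tmp_path, tiny_config):
        d1, d2 = tmp_path / "a", tmp_path / "b"
        generate_genome(tiny_config).write(d1)
        generate_genome(tiny_config).write(d2)
        for name in ("genome.fa", "genes.gff3", "triads.tsv", "truth_acrs.tsv"):
            assert (d1 / name).read_bytes() == (d2 / name).read_bytes()

    def test_no_responsive_when_fraction_zero(self):
        cfg = SyntheticConfig(n_triads=20, n_singletons=3, chrom_length=150_000,
                              frac_responsive_acrs=0.0, seed=1)
        truth = generate_genome(cfg).truth
        assert len(truth.responsive_acrs()) == 0
        assert (truth.genes.direction == "stable").all()

    def test_homoeolog_identity_at_least_85pct(self, tiny_genome):
        truth = tiny_genome.truth
        row = truth.triads.iloc[0]
        ga = truth.genes.set_index("gene_id")
        seqs = []
        for gid in (row.gene_A, row.gene_B, row.gene_D):
            g = ga.loc[gid]
            seqs.append(tiny_genome.sequence_str(g.chrom, g.start, g.end))
        for a, b in ((0, 1), (0, 2), (1, 2)):
            ident = np.mean([x == y for x, y in zip(seqs[a], seqs[b])])
            assert ident >= 0.85

    def test_acrs_within_bounds(self, tiny_genome):
        truth = tiny_genome.truth
        for r in truth.acrs.itertuples():
            assert 0 <= r.start < r.end <= truth.chrom_sizes[r.chrom]

    def test_cre_gc_elevated_over_background(self, tiny_genome):
        truth = tiny_genome.truth
        distal = truth.acrs[truth.acrs.cre_class != "promoter"]
        gcs = []
        for r in distal.itertuples():
            s = tiny_genome.sequence_str(r.chrom, r.start, r.end)
            gcs.append((s.count("G") + s.count("C")) / len(s))
        bg = tiny_genome.sequence_str("chr1A", 0, 3000)
        bg_gc = (bg.count("G") + bg.count("C")) / len(bg)
        assert np.mean(gcs) - bg_gc >= 0.05

    def test_planted_motif_substring_present(self, tiny_genome):
        truth = tiny_genome.truth
        with_motif = truth.acrs[truth.acrs.has_motif]
        assert len(with_motif) > 0
        for r in with_motif.itertuples():
            s = tiny_genome.sequence_str(r.chrom, r.start, r.end)
            assert SPL_CONSENSUS in s and "GTAC" in s

    @pytest.mark.parametrize("field,value", [
        ("n_triads", 0), ("frac_responsive_acrs", 1.5),
        ("nb_dispersion", 0.0), ("chrom_length", 10_000),
    ])
    def test_config_errors_name_the_field(self, field, value):
        cfg = SyntheticConfig(**{field: value})
        with pytest.raises(ConfigError):
            cfg.validate()

    def test_truth_tables_round_trip(self, tmp_path, tiny_genome):
        tiny_genome.truth.write(tmp_path)
        acrs, genes, triads = GroundTruth.read_tables(tmp_path)
        assert len(acrs) == len(tiny_genome.truth.acrs)
        assert (acrs.acr_id == tiny_genome.truth.acrs.acr_id).all()
        assert (genes.gene_id == tiny_genome.truth.genes.gene_id).all()


class TestTISTrack:
    def test_library_size_near_target(self, tiny_genome, tiny_config):
        track, lib = simulate_tis_track(tiny_genome, tiny_genome.truth, "before", 1)
        assert abs(lib - tiny_config.library_size) / tiny_config.library_size < 0.05

    def test_unknown_condition_rejected(self, tiny_genome):
        with pytest.raises(ValueError, match="condition"):
            simulate_tis_track(tiny_genome, tiny_genome.truth, "sometime", 1)

    def test_generative_fold_for_induced_acr(self, tiny_genome, tiny_config):
        """Mean density ratio after/before ~ 2^log2fc over 10 replicates."""
        truth = tiny_genome.truth
        resp = truth.acrs[truth.acrs.response == "induced"]
        assert len(resp) > 0
        r = resp.iloc[0]
        before, after = [], []
        for rep in range(1, 11):
            tb, _ = simulate_tis_track(tiny_genome, truth, "before", rep)
            ta, _ = simulate_tis_track(tiny_genome, truth, "after", rep)
            before.append(tb[r.chrom][r.start:r.end].mean())
            after.append(ta[r.chrom][r.start:r.end].mean())
        ratio = np.mean(after) / np.mean(before)
        assert 3.5 <= ratio <= 4.5

    def test_enrichment_factor_inside_acrs(self):
        cfg = SyntheticConfig(n_triads=20, n_singletons=3, chrom_length=150_000,
                              frac_responsive_acrs=0.0, seed=2)
        genome = generate_genome(cfg)
        truth = genome.truth
        track, _ = simulate_tis_track(genome, truth, "before", 1)
        mask = {c: np.zeros(n, bool) for c, n in truth.chrom_sizes.items()}
        for r in truth.acrs.itertuples():
            mask[r.chrom][r.start:r.end] = True
        inside = np.concatenate([track[c][mask[c]] for c in track]).mean()
        outside = np.concatenate([track[c][~mask[c]] for c in track]).mean()
        assert 7.0 <= inside / outside <= 9.0


class TestMarkTracks:
    def test_k4_peak_near_planted_k4_dacr(self, tiny_genome):
        truth = tiny_genome.truth
        marks = simulate_mark_tracks(tiny_genome, truth, "before")
        k4_idx = IntervalIndex(marks["H3K4me3"][1])
        k4d = truth.acrs[truth.acrs.cre_class == "K4-dACR"]
        assert len(k4d) > 0
        for r in k4d.itertuples():
            probe = Interval(r.chrom, max(0, r.start - 500), r.end + 500)
            assert k4_idx.any_overlap(probe)

    def test_mixed_gene_carries_both_marks(self, tiny_genome):
        truth = tiny_genome.truth
        mixed = truth.genes[truth.genes.state_before == "mixed"]
        if len(mixed) == 0:
            pytest.skip("no mixed gene drawn in tiny genome")
        marks = simulate_mark_tracks(tiny_genome, truth, "before")
        ac = IntervalIndex(marks["H3K27ac"][1])
        me = IntervalIndex(marks["H3K27me3"][1])
        g = mixed.iloc[0]
        body = Interval(g.chrom, g.start, g.end)
        assert ac.any_overlap(body) and me.any_overlap(body)

    def test_unmodified_truth_gives_background_only(self):
        cfg = SyntheticConfig(n_triads=20, n_singletons=3, chrom_length=150_000,
                              seed=3)
        genome = generate_genome(cfg)
        truth = genome.truth
        # force everything unmodified
        truth.genes["state_before"] = "unmodified"
        truth.acrs["mod_label"] = "U"
        truth.acrs["cre_class"] = truth.acrs.cre_class.replace("K4-dACR", "nK4-dACR")
        from verncre.synthetic import _build_mark_domains
        truth.mark_domains.clear()
        _build_mark_domains(truth)
        marks = simulate_mark_tracks(genome, truth, "before")
        for mark, (track, peaks) in marks.items():
            assert peaks == []
            mean = np.mean([track[c].mean() for c in track])
            assert mean < 0.05  # pure background


class TestExpression:
    def test_zero_mean_gene_all_zero(self, tiny_genome):
        truth = tiny_genome.truth
        counts = simulate_expression(tiny_genome, truth)
        zero = truth.genes[truth.genes.mean_before == 0]
        if len(zero):
            assert (counts.loc[zero.gene_id, ["before_1", "before_2"]] == 0).all().all()

    def test_balanced_triad_proportions(self):
        cfg = SyntheticConfig(n_triads=60, n_singletons=3, chrom_length=400_000,
                              frac_responsive_acrs=0.0, seed=4)
        genome = generate_genome(cfg)
        truth = genome.truth
        counts = simulate_expression(genome, truth)
        ba = truth.triads[truth.triads.category == "Ba"]
        assert len(ba) >= 30
        props = []
        for r in ba.itertuples():
            v = counts.loc[[r.gene_A, r.gene_B, r.gene_D]].mean(axis=1).to_numpy()
            props.append(v / v.sum())
        mean_props = np.mean(props, axis=0)
        assert np.allclose(mean_props, 1 / 3, atol=0.05)

    def test_depth_factor_scales_counts(self, tiny_genome):
        truth = tiny_genome.truth
        c1 = simulate_expression(tiny_genome, truth, depth_factor=1.0)
        c2 = simulate_expression(tiny_genome, truth, depth_factor=2.0)
        expressed = truth.genes.mean_before > 10
        ratio = (c2.loc[expressed.to_numpy(), "before_1"].mean()
                 / c1.loc[expressed.to_numpy(), "before_1"].mean())
        assert 1.7 <= ratio <= 2.3


class TestAuxiliaryFeatures:
    def test_all_gwas_near_cre_when_fraction_one(self):
        cfg = SyntheticConfig(n_triads=20, n_singletons=3, chrom_length=150_000,
                              frac_gwas_near_cre=1.0, n_gwas=50, seed=5)
        genome = generate_genome(cfg)
        aux = plant_auxiliary_features(genome, genome.truth)
        resp = genome.truth.responsive_acrs()
        idx = IntervalIndex([
            Interval(r.chrom, int(r.start), int(r.end)) for r in resp.itertuples()
        ])
        for s in aux["gwas"]:
            assert idx.any_overlap(Interval(s.chrom, max(0, s.start - 1001), s.end + 1001))

    def test_snp_depletion_factor_one_is_neutral(self):
        cfg = SyntheticConfig(n_triads=40, n_singletons=3, chrom_length=300_000,
                              snp_depletion=1.0, seed=6)
        genome = generate_genome(cfg)
        truth = genome.truth
        aux = plant_auxiliary_features(genome, truth)
        mask = {c: np.zeros(n, bool) for c, n in truth.chrom_sizes.items()}
        for r in truth.acrs.itertuples():
            mask[r.chrom][r.start:r.end] = True
        pos = {c: np.zeros(n, bool) for c, n in truth.chrom_sizes.items()}
        for s in aux["snps"]:
            pos[s.chrom][s.start] = True
        inside = np.concatenate([pos[c][mask[c]] for c in pos]).mean()
        outside = np.concatenate([pos[c][~mask[c]] for c in pos]).mean()
        assert 0.8 <= inside / outside <= 1.25

    def test_te_superfamily_codes(self, tiny_genome):
        aux = plant_auxiliary_features(tiny_genome, tiny_genome.truth)
        codes = {t.name for t in aux["tes"]}
        assert codes <= {"DTT", "DTX", "RLG", "RLC", "RIX", "other"}

    def test_emitted_files_parse_with_readers(self, tmp_path, tiny_config):
        from verncre.synthetic import write_all_tracks
        genome = generate_genome(tiny_config)
        write_all_tracks(genome, tmp_path)
        sizes = {c: len(s) for c, s in read_fasta(tmp_path / "genome.fa").items()}
        assert sizes == genome.chrom_sizes
        genes = read_gff3(tmp_path / "genes.gff3")
        assert len(genes) == len(genome.genes)
        track = read_bedgraph(tmp_path / "tis_before_1.bedgraph", sizes)
        assert sum(a.sum() for a in track.values()) > 0
        assert len(read_bed(tmp_path / "snps.bed")) > 0
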