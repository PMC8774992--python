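"""Generative model: determinism, truth-set soundness, moment checks."""

import numpy as np
import pytest

from motifmk.annotation import read_gff3, write_gff3
from motifmk.genome import revcomp
from motifmk.orthomap import snp_positions
from motifmk.phylo import FIXTURE_TREE_9
from motifmk.scan import scan_motif
from motifmk.simulate import (
    SimConfig,
    simulate_annotation,
    simulate_bm_traits,
    simulate_chip,
    simulate_divergence,
    simulate_genome,
    simulate_polymorphism,
    simulate_segment_records,
)


class TestConfig:
    def test_rejects_bad_values(self):
        with pytest.raises(ValueError):
            SimConfig(gc_content=1.5)
        with pytest.raises(ValueError):
            SimConfig(chrom_specs=(("c", 0, "autosome"),))
        with pytest.raises(ValueError):
            SimConfig(motif="ACGU")
        with pytest.raises(ValueError):
            SimConfig(chrom_specs=(("c", 100, "plasmid"),))

    def test_substreams_independent(self):
        cfg = SimConfig(seed=3)
        a = cfg.rng("genome").integers(0, 1000, 5)
        b = cfg.rng("divergence").integers(0, 1000, 5)
        assert not np.array_equal(a, b)
        assert np.array_equal(a, cfg.rng("genome").integers(0, 1000, 5))


class TestSimulateGenome:
    def test_no_planting(self):
        cfg = SimConfig(n_motifs=0, chrom_specs=(("c", 1000, "autosome"),))
        _, truth = simulate_genome(cfg)
        assert truth == []

    def test_truth_is_subset_of_scan(self):
        cfg = SimConfig(seed=5, n_motifs=50,
                        chrom_specs=(("c", 100_000, "autosome"),))
        genome, truth = simulate_genome(cfg)
        found = {(i.chrom, i.start, i.strand) for i in scan_motif(genome, cfg.motif)}
        assert len(found) >= 50
        assert {(t.chrom, t.start, t.strand) for t in truth} <= found

    def test_planted_sequences_match_motif(self):
        cfg = SimConfig(seed=5, n_motifs=30, chrom_specs=(("c", 50_000, "autosome"),))
        genome, truth = simulate_genome(cfg)
        for t in truth:
            planted = genome.chroms[t.chrom][t.start:t.end]
            assert planted == (cfg.motif if t.strand == "+" else revcomp(cfg.motif))

    def test_plants_never_overlap(self):
        cfg = SimConfig(seed=5, n_motifs=200, chrom_specs=(("c", 20_000, "autosome"),))
        _, truth = simulate_genome(cfg)
        by_chrom = sorted((t.chrom, t.start, t.end) for t in truth)
        for (c1, s1, e1), (c2, s2, e2) in zip(by_chrom, by_chrom[1:]):
            assert c1 != c2 or s2 >= e1

    def test_exon_proximity_bias_forced(self):
        cfg = SimConfig(seed=5, n_motifs=40, n_genes=10,
                        exon_proximity_bias=1.0,
                        chrom_specs=(("c", 100_000, "autosome"),))
        genes = simulate_annotation(cfg)
        genome, truth = simulate_genome(cfg, genes=genes)
        from motifmk.annotation import exon_intervals
        from motifmk.scan import exon_proximity_fraction

        assert exon_proximity_fraction(truth, exon_intervals(genes)) == 1.0

    def test_infeasible_placement_rejected(self):
        with pytest.raises(ValueError):
            simulate_genome(
                SimConfig(n_motifs=200, chrom_specs=(("c", 1000, "autosome"),))
            )
        with pytest.raises(ValueError):
            simulate_genome(
                SimConfig(motif="A" * 2000, chrom_specs=(("c", 1000, "autosome"),),
                          n_motifs=0)
            )

    def test_byte_identical_under_same_seed(self, small_config):
        g1, t1 = simulate_genome(small_config)
        g2, t2 = simulate_genome(small_config)
        assert g1.chroms == g2.chroms and t1 == t2

    def test_gc_content_close(self):
        cfg = SimConfig(seed=2, gc_content=0.3, n_motifs=0,
                        chrom_specs=(("c", 100_000, "autosome"),))
        genome, _ = simulate_genome(cfg)
        seq = genome.chroms["c"]
        gc = (seq.count("G") + seq.count("C")) / len(seq)
        assert gc == pytest.approx(0.3, abs=0.01)


class TestSimulateDivergence:
    def test_zero_rate_is_identity(self, small_config):
        genome, truth = simulate_genome(small_config)
        cfg = small_config.replace(mu_core=0.0, mu_flank=0.0)
        derived, blocks, log = simulate_divergence(genome, truth, cfg)
        assert derived.chroms == genome.chroms
        assert len(log) == 0

    def test_flank_substitution_count_binomial(self):
        # 10^6 flank sites at mu=0.01: expect 10^4 +- 3 binomial SD
        cfg = SimConfig(seed=9, n_motifs=0, mu_flank=0.01, mu_core=0.1,
                        chrom_specs=(("c", 1_000_000, "autosome"),))
        genome, truth = simulate_genome(cfg)
        _, _, log = simulate_divergence(genome, truth, cfg)
        n, p = 1_000_000, 0.01
        sd = np.sqrt(n * p * (1 - p))
        assert abs(len(log) - n * p) < 3 * sd

    def test_core_sites_hit_at_core_rate(self):
        cfg = SimConfig(seed=9, n_motifs=500, mu_flank=0.0, mu_core=0.5,
                        chrom_specs=(("c", 200_000, "autosome"),))
        genome, truth = simulate_genome(cfg)
        _, _, log = simulate_divergence(genome, truth, cfg)
        assert (log["site_class"] == "core").all()
        n_core = 500 * 7
        sd = np.sqrt(n_core * 0.25)
        assert abs(len(log) - n_core * 0.5) < 3 * sd

    def test_identity_blockmap_by_default(self, small_config):
        genome, truth = simulate_genome(small_config)
        _, blocks, _ = simulate_divergence(genome, truth, small_config)
        assert len(blocks) == len(genome.chroms)
        assert (blocks["identity"] == 1.0).all()
        assert (blocks["src_start"] == blocks["dst_start"]).all()

    def test_block_shuffle_fragments(self, small_config):
        genome, truth = simulate_genome(small_config)
        _, blocks, _ = simulate_divergence(
            genome, truth, small_config, block_shuffle=5, block_identity_jitter=0.2
        )
        assert len(blocks) == 5 * len(genome.chroms)
        assert (blocks["identity"] <= 1.0).all() and (blocks["identity"] >= 0.8).all()


class TestSimulatePolymorphism:
    def test_zero_theta_empty(self, small_config):
        genome, truth = simulate_genome(small_config)
        cfg = small_config.replace(theta_core=0.0, theta_flank=0.0)
        assert simulate_polymorphism(genome, truth, cfg).empty

    def test_low_maf_point_mass_filtered_out(self):
        cfg = SimConfig(seed=4, n_motifs=0, theta_flank=0.01, maf_spectrum=0.02,
                        chrom_specs=(("c", 50_000, "autosome"),))
        genome, truth = simulate_genome(cfg)
        variants = simulate_polymorphism(genome, truth, cfg)
        assert len(variants) > 0
        assert snp_positions(variants, maf_min=0.05) == {}

    def test_snp_count_binomial(self):
        cfg = SimConfig(seed=4, n_motifs=0, theta_flank=0.01,
                        chrom_specs=(("c", 100_000, "autosome"),))
        genome, truth = simulate_genome(cfg)
        variants = simulate_polymorphism(genome, truth, cfg)
        n, p = 100_000, 0.01
        sd = np.sqrt(n * p * (1 - p))
        assert abs(len(variants) - n * p) < 3 * sd

    def test_alt_differs_from_ref(self, small_config):
        genome, truth = simulate_genome(small_config)
        variants = simulate_polymorphism(genome, truth, small_config)
        assert (variants["ref"] != variants["alt"]).all()
        assert variants["is_snp"].all()  # default indel_fraction = 0


class TestSimulateAnnotation:
    def test_empty(self):
        assert simulate_annotation(SimConfig(n_genes=0)) == []

    def test_genes_valid_and_non_overlapping(self, small_config):
        genes = simulate_annotation(small_config)
        assert len(genes) == small_config.n_genes
        by_chrom: dict = {}
        for g in genes:
            assert g.exons and all(g.start <= s < e <= g.end for s, e in g.exons)
            by_chrom.setdefault(g.chrom, []).append((g.start, g.end))
        for ivs in by_chrom.values():
            ivs.sort()
            assert all(a[1] <= b[0] for a, b in zip(ivs, ivs[1:]))

    def test_tss_respects_strand(self, small_config):
        for g in simulate_annotation(small_config):
            assert g.tss == (g.start if g.strand == "+" else g.end - 1)

    def test_gff3_round_trip(self, small_config, tmp_path):
        genes = simulate_annotation(small_config)
        path = tmp_path / "genes.gff3"
        write_gff3(genes, path)
        back = read_gff3(path)
        assert [(g.gene_id, g.chrom, g.start, g.end, g.strand, g.exons)
                for g in genes] == [
            (g.gene_id, g.chrom, g.start, g.end, g.strand, g.exons) for g in back
        ]

    def test_rejects_too_many_genes(self):
        with pytest.raises(ValueError):
            simulate_annotation(
                SimConfig(n_genes=100, chrom_specs=(("c", 10_000, "autosome"),))
            )


class TestSimulateChip:
    def test_zero_reads_all_zero(self, small_config):
        from motifmk.chip import tss_window_counts

        genes = simulate_annotation(small_config)
        cfg = small_config.replace(chip_background_reads=0, chip_enrichment=1.0)
        reads, _ = simulate_chip(genes, [], cfg)
        matrix = tss_window_counts(
            {f"{f}_r{r}": df for (f, r), df in reads.items()}, genes
        )
        assert (matrix.values == 0).all().all()

    def test_bound_genes_rank_high(self, small_config):
        from motifmk.chip import normalize_signal, tss_window_counts

        genes = simulate_annotation(small_config)
        bound = [g.gene_id for g in genes[:3]]  # top decile of 30 genes
        cfg = small_config.replace(chip_enrichment=10.0)
        reads, _ = simulate_chip(genes, bound, cfg, factor_effect_sd=0.0)
        matrix = normalize_signal(
            tss_window_counts({f"{f}_r{r}": df for (f, r), df in reads.items()}, genes)
        )
        mean_signal = matrix.values.mean(axis=1)
        top_decile = set(mean_signal.nlargest(len(genes) // 10).index)
        assert set(bound) <= top_decile

    def test_replicate_and_peak_structure(self, small_config):
        genes = simulate_annotation(small_config)
        bound = [genes[0].gene_id]
        reads, peaks = simulate_chip(genes, bound, small_config)
        factors = set(small_config.chip_factors)
        assert {f for f, _ in reads} == factors
        assert all(r in range(1, 5) for _, r in reads)
        for (f, r), pk in peaks.items():
            assert (pk["chrom"].isin([c for c, _, _ in small_config.chrom_specs])).all()


class TestSimulateBMTraits:
    def test_zero_variance_all_equal_root(self):
        traits = simulate_bm_traits(FIXTURE_TREE_9, sigma2=0.0, root_value=3.5)
        assert all(v == 3.5 for v in traits.values())

    def test_two_tip_variance_closed_form(self):
        tree = "(a:1,b:1);"
        diffs = [
            simulate_bm_traits(tree, sigma2=2.0, seed=s)
            for s in range(4000)
        ]
        d = np.array([t["a"] - t["b"] for t in diffs])
        # Var(a - b) = sigma2 * (l_a + l_b) = 4
        assert np.var(d) == pytest.approx(4.0, rel=0.1)

    def test_group_effect_added(self):
        traits = simulate_bm_traits(
            FIXTURE_TREE_9, sigma2=0.0, group_effect=5.0, effect_tips=("dmel",)
        )
        assert traits["dmel"] == 5.0 and traits["dvir"] == 0.0


class TestSegmentRecords:
    def test_schema_and_class_layout(self):
        rec = simulate_segment_records(10, 0.1, 0.05, 0.02, 0.05, seed=1)
        assert list(rec.columns) == [
            "segment", "chrom", "pos", "site_class", "fixed_diff", "polymorphic"
        ]
        one = rec[rec["segment"] == 0]
        assert len(one) == 21
        assert (one["site_class"].to_numpy()[7:14] == "core").all()
        assert (one["site_class"].to_numpy()[:7] == "flank").all()

    def test_no_double_counting(self):
        rec = simulate_segment_records(500, 0.5, 0.5, 0.5, 0.5, seed=2)
        assert not ((rec["fixed_diff"] == 1) & (rec["polymorphic"] == 1)).any()

    def test_rates_match_binomial_expectation(self):
        n_seg = 10_000  # 7e4 core sites
        rec = simulate_segment_records(n_seg, 0.1, 0.0, 0.0, 0.0, seed=3)
        n_core = 7 * n_seg
        d = rec.loc[rec["site_class"] == "core", "fixed_diff"].sum()
        sd = np.sqrt(n_core * 0.1 * 0.9)
        assert abs(d - 0.1 * n_core) < 3 * sd
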