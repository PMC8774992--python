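"""TSS-window signal, normalization, clustering, enrichment, peaks."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from motifmk.annotation import GeneModel
from motifmk.chip import (
    Peak,
    SignalMatrix,
    bound_genes,
    chromosome_enrichment,
    intersect_replicate_peaks,
    normalize_signal,
    pca_cluster_check,
    permutation_test,
    protein_divergence,
    rank_replicate_pairs,
    tss_window_counts,
)
from motifmk.simulate import SimConfig, simulate_annotation, simulate_chip


def brute_force_counts(reads, genes, half_width):
    """Oracle: explicit containment check per read per gene."""
    out = {}
    for g in genes:
        lo, hi = g.tss - half_width, g.tss + half_width
        out[g.gene_id] = sum(
            1 for _, r in reads.iterrows()
            if r["chrom"] == g.chrom and lo <= r["pos"] <= hi
        )
    return out


class TestWindowCounts:
    def test_zero_reads(self, simple_genes):
        m = tss_window_counts({"s1": pd.DataFrame(columns=["chrom", "pos"])},
                              simple_genes)
        assert (m.values["s1"] == 0).all()

    def test_read_exactly_at_tss(self, simple_genes):
        reads = {"s1": pd.DataFrame(dict(chrom=["chr2L"], pos=[2000]))}
        m = tss_window_counts(reads, simple_genes)
        assert m.values.loc["gA", "s1"] == 1

    def test_window_boundaries_closed(self):
        gene = GeneModel("g", "c", 1000, 2000, "+", ((1000, 2000),))
        reads = {"s": pd.DataFrame(dict(chrom=["c"] * 4,
                                        pos=[649, 650, 1350, 1351]))}
        m = tss_window_counts(reads, [gene], half_width=350)
        assert m.values.loc["g", "s"] == 2  # 650 and 1350 inside [650, 1350]

    def test_matches_brute_force_oracle(self, rng, simple_genes):
        reads = {
            "s1": pd.DataFrame(dict(
                chrom=rng.choice(["chr2L", "chrX"], size=2000),
                pos=rng.integers(0, 8000, size=2000),
            ))
        }
        for hw in (100, 350, 500):
            m = tss_window_counts(reads, simple_genes, half_width=hw)
            oracle = brute_force_counts(reads["s1"], simple_genes, hw)
            assert m.values["s1"].to_dict() == oracle


class TestNormalize:
    def matrix(self, values):
        df = pd.DataFrame(values, columns=["s1", "s2"])
        meta = pd.DataFrame({"factor": ["a", "b"], "replicate": [1, 1]},
                            index=["s1", "s2"])
        return SignalMatrix(df, meta)

    def test_constant_sample_all_ones(self):
        m = normalize_signal(self.matrix([[5, 2], [5, 4], [5, 6]]))
        assert (m.values["s1"] == 1.0).all()
        assert m.values.mean(axis=0).round(9).eq(1.0).all()

    def test_scale_invariance_and_idempotence(self):
        m1 = normalize_signal(self.matrix([[1, 2], [3, 4], [5, 6]]))
        m2 = normalize_signal(self.matrix([[2, 2], [6, 4], [10, 6]]))
        assert np.allclose(m1.values["s1"], m2.values["s1"])
        again = normalize_signal(m1)
        assert np.allclose(again.values, m1.values)

    def test_hand_computed(self):
        m = normalize_signal(self.matrix([[1, 1], [2, 1], [3, 1]]))
        assert list(m.values["s1"]) == [0.5, 1.0, 1.5]

    def test_all_zero_sample_errors(self):
        with pytest.raises(ValueError):
            normalize_signal(self.matrix([[0, 1], [0, 2], [0, 3]]))


def make_design(rng, n_genes=200, n_factors=3, n_reps=4, effect=5.0, noise=1.0):
    """Factor-specific mean profiles plus replicate noise."""
    base = rng.gamma(2.0, 2.0, size=n_genes)
    values, factors = {}, {}
    for f in range(n_factors):
        shift = rng.normal(0, effect, size=n_genes)
        for r in range(n_reps):
            sid = f"f{f}_r{r}"
            values[sid] = np.abs(base + shift + rng.normal(0, noise, size=n_genes))
            factors[sid] = f"f{f}"
    df = pd.DataFrame(values, index=[f"g{i}" for i in range(n_genes)])
    meta = pd.DataFrame({"factor": pd.Series(factors), "replicate": 1})
    return SignalMatrix(df, meta)


class TestPCACluster:
    def test_strong_factor_effects_cluster(self, rng):
        m = make_design(rng, effect=5.0, noise=0.5)
        _, sil = pca_cluster_check(m)
        assert sil > 0.5

    def test_identical_replicates_silhouette_near_one(self, rng):
        m = make_design(rng, effect=5.0, noise=0.0)
        _, sil = pca_cluster_check(m)
        assert sil > 0.99

    def test_label_permutation_destroys_silhouette(self, rng):
        m = make_design(rng, effect=5.0, noise=0.5)
        _, sil = pca_cluster_check(m)
        perm = m.samples.copy()
        perm["factor"] = rng.permutation(perm["factor"].to_numpy())
        _, sil_perm = pca_cluster_check(SignalMatrix(m.values, perm))
        assert sil_perm < sil

    def test_too_few_samples(self, rng):
        m = make_design(rng, n_factors=1, n_reps=2)
        with pytest.raises(ValueError):
            pca_cluster_check(m)


class TestProteinDivergence:
    def test_self_distance_zero_and_null_p(self, rng):
        m = make_design(rng, effect=0.0, noise=1.0)
        d_a, d_b, p = protein_divergence(m, "f0", "f1", "f2", n_perm=200, seed=rng)
        assert d_a > 0 and d_b > 0
        assert p > 0.01  # same generative process: unremarkable

    def test_constructed_extra_divergence_detected(self, rng):
        # 6 replicates/factor: the group-relabelling null has C(12,6) = 924
        # distinct splits, so p can resolve below 0.01
        m = make_design(rng, effect=0.0, noise=0.5, n_reps=6)
        vals = m.values.copy()
        # shared profile shift pushes factor f0 away from the reference
        shift = rng.normal(0, 6.0, size=len(vals))
        for c in m.samples.index[m.factors == "f0"]:
            vals[c] = np.abs(vals[c] + shift)
        m2 = SignalMatrix(vals, m.samples)
        d_a, d_b, p = protein_divergence(m2, "f0", "f1", "f2", n_perm=300, seed=1)
        assert d_a > d_b
        assert p < 0.01


class TestChromosomeEnrichment:
    def genes(self, n_per_chrom=60):
        out = []
        for chrom in ("chrX", "chr2L", "chr3R"):
            for i in range(n_per_chrom):
                s = 2000 * i + 100
                out.append(GeneModel(f"{chrom}_g{i}", chrom, s, s + 1000, "+",
                                     ((s, s + 1000),)))
        return out

    def classes(self):
        return {"chrX": "X", "chr2L": "autosome", "chr3R": "autosome"}

    def build_matrix(self, rng, x_fold_by_factor):
        genes = self.genes()
        values, factors = {}, {}
        for f, fold in x_fold_by_factor.items():
            for r in range(3):
                sid = f"{f}_r{r}"
                v = rng.gamma(5.0, 1.0, size=len(genes))
                for i, g in enumerate(genes):
                    if g.chrom == "chrX":
                        v[i] *= fold
                values[sid] = v
                factors[sid] = f
        df = pd.DataFrame(values, index=[g.gene_id for g in genes])
        meta = pd.DataFrame({"factor": pd.Series(factors), "replicate": 1})
        return SignalMatrix(df, meta), genes

    def test_uniform_signal_null(self, rng):
        m, genes = self.build_matrix(rng, {"a": 1.0})
        medians, p = chromosome_enrichment(m, genes, self.classes(),
                                           n_perm=300, seed=rng)
        assert p["a"] > 0.01

    def test_planted_x_enrichment_detected(self, rng):
        m, genes = self.build_matrix(rng, {"enriched": 5.0, "flat": 1.0})
        medians, p = chromosome_enrichment(m, genes, self.classes(),
                                           n_perm=2000, seed=rng)
        assert p["enriched"] < 0.001
        assert p["flat"] > 0.01
        assert medians.loc["chrX", "enriched"] > medians.loc["chr2L", "enriched"]

    def test_medians_invariant_to_rescaling(self, rng):
        m, genes = self.build_matrix(rng, {"a": 2.0})
        med1, _ = chromosome_enrichment(m, genes, self.classes(), n_perm=10, seed=0)
        m2 = SignalMatrix(m.values * 3.0, m.samples)
        med2, _ = chromosome_enrichment(m2, genes, self.classes(), n_perm=10, seed=0)
        assert np.allclose(med2.to_numpy(), 3.0 * med1.to_numpy())


class TestPeaks:
    def test_identical_inputs(self):
        peaks = [Peak("c", 100, 200), Peak("c", 300, 400)]
        assert intersect_replicate_peaks(peaks, peaks) == peaks

    def test_disjoint_inputs_empty(self):
        assert intersect_replicate_peaks([Peak("c", 0, 100)],
                                         [Peak("c", 200, 300)]) == []

    def test_hand_constructed_intersections(self):
        rep1 = [Peak("c", 0, 150), Peak("c", 200, 400), Peak("c", 500, 600)]
        rep2 = [Peak("c", 100, 250), Peak("c", 390, 550)]
        got = intersect_replicate_peaks(rep1, rep2)
        assert got == [Peak("c", 100, 150), Peak("c", 200, 250),
                       Peak("c", 390, 400), Peak("c", 500, 550)]

    def test_bound_genes(self, simple_genes):
        assert bound_genes([], simple_genes) == set()
        assert bound_genes([Peak("chr2L", 2500, 2550)], simple_genes) == {"gA"}
        # peak spanning two genes returns both
        wide = [Peak("chr2L", 2900, 6100)]
        assert bound_genes(wide, simple_genes) == {"gA", "gB"}

    def test_rank_replicates_prefers_correlated_pair(self, rng):
        base = rng.gamma(2, 2, size=100)
        values = pd.DataFrame({
            "r1": base + rng.normal(0, 0.1, 100),
            "r2": base + rng.normal(0, 0.1, 100),
            "r3": rng.gamma(2, 2, size=100),
        })
        meta = pd.DataFrame({"factor": ["f"] * 3, "replicate": [1, 2, 3]},
                            index=values.columns)
        ranked = rank_replicate_pairs(SignalMatrix(values, meta), "f")
        assert set(ranked[0][:2]) == {"r1", "r2"}


class TestPermutationTest:
    def test_identical_samples_p_one(self):
        a = [1.0, 2.0, 3.0, 4.0]
        assert permutation_test(a, a, n_perm=100, seed=0) == 1.0

    def test_power(self, rng):
        a = rng.normal(0, 1, 50)
        b = rng.normal(3, 1, 50)
        assert permutation_test(a, b, n_perm=2000, seed=rng) < 0.001

    def test_null_p_uniform(self, rng):
        ps = [
            permutation_test(rng.normal(0, 1, 20), rng.normal(0, 1, 20),
                             n_perm=99, seed=rng)
            for _ in range(300)
        ]
        assert all(0 < p <= 1 for p in ps)
        ks = stats.kstest(ps, "uniform")
        assert ks.pvalue > 0.001

    def test_median_statistic(self, rng):
        a = rng.normal(0, 1, 40)
        b = rng.normal(2, 1, 40)
        assert permutation_test(a, b, stat="median", n_perm=500, seed=1) < 0.01


class TestEndToEndChipSim:
    def test_simulated_design_clusters_and_detects_enrichment(self):
        cfg = SimConfig(
            seed=33,
            chrom_specs=(("chr2L", 120_000, "autosome"), ("chrX", 80_000, "X")),
            n_genes=80,
            chip_enrichment=8.0,
        )
        genes = simulate_annotation(cfg)
        rng = np.random.default_rng(12)
        gene_ids = [g.gene_id for g in genes]
        bound = {f: list(rng.choice(gene_ids, size=20, replace=False))
                 for f in cfg.chip_factors}
        x_fold = {cfg.chip_factors[1]: {"chrX": 5.0}}
        reads, _ = simulate_chip(genes, bound, cfg, factor_chrom_fold=x_fold)
        meta = pd.DataFrame(
            {"factor": [f for f, _ in reads], "replicate": [r for _, r in reads]},
            index=[f"{f}_r{r}" for f, r in reads],
        )
        matrix = tss_window_counts(
            {f"{f}_r{r}": df for (f, r), df in reads.items()}, genes, samples=meta
        )
        norm = normalize_signal(matrix)
        _, sil = pca_cluster_check(norm)
        assert sil > 0.2  # distinct bound sets separate the factors
        classes = {"chr2L": "autosome", "chrX": "X"}
        _, p = chromosome_enrichment(norm, genes, classes, n_perm=500, seed=5)
        assert p[cfg.chip_factors[1]] < 0.01
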