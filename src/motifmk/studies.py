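"""Desk-scale calibration, recovery and control studies.

These routines run the package's own machinery over replicated synthetic
data under known regimes: bootstrap-CI coverage and G-test type-I error
under the fully neutral model, recovery of the analytic adaptive
fraction alpha* under the selection regime, the shuffled-motif control
battery on a genome where selection acts only at focal-motif cores, a
replicated ChIP design with a planted X-chromosome affinity, and type-I
calibration of the phylogenetic ANOVA under its Brownian-motion null.

Default problem sizes (2000 segments, 100 pipeline replicates, 1000 G
tables, 500 phylogenetic runs) are the package's standard desk-scale
study conditions.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from . import chip, mk, phylo, scan, simulate
from .orthomap import BlockMap

NEUTRAL_RATES = dict(mu_core=0.05, mu_flank=0.05, theta_core=0.05, theta_flank=0.05)
ADAPTIVE_RATES = dict(mu_core=0.2, mu_flank=0.05, theta_core=0.05, theta_flank=0.05)

#: Analytic adaptive fraction implied by ADAPTIVE_RATES.
ALPHA_STAR = 1.0 - (
    ADAPTIVE_RATES["mu_flank"] * ADAPTIVE_RATES["theta_core"]
) / (ADAPTIVE_RATES["mu_core"] * ADAPTIVE_RATES["theta_flank"])


def neutral_ci_coverage(
    n_reps: int = 100,
    n_segments: int = 2000,
    n_boot: int = 1000,
    level: float = 0.99,
    seed: int = 0,
) -> dict:
    """Fraction of neutral replicates whose bootstrap CI covers alpha = 0."""
    root = np.random.SeedSequence(seed).spawn(n_reps)
    covered = 0
    for r in range(n_reps):
        gen_rng, boot_rng = [np.random.default_rng(s) for s in root[r].spawn(2)]
        rec = simulate.simulate_segment_records(
            n_segments, **NEUTRAL_RATES, seed=gen_rng
        )
        est = mk.bootstrap_alpha(rec, n_boot=n_boot, level=level, seed=boot_rng)
        covered += est.ci_low <= 0.0 <= est.ci_high
    return dict(covered=covered, n_reps=n_reps, coverage=covered / n_reps)


def g_test_type_i(
    n_tables: int = 1000,
    n_segments: int = 2000,
    alpha_level: float = 0.05,
    seed: int = 0,
) -> dict:
    """G-test rejection rate on tables drawn from the neutral model."""
    root = np.random.SeedSequence(seed).spawn(n_tables)
    rejections = 0
    for r in range(n_tables):
        rec = simulate.simulate_segment_records(
            n_segments, **NEUTRAL_RATES, seed=np.random.default_rng(root[r])
        )
        p_g, _ = mk.mk_tests(mk.build_mk_table(rec))
        rejections += p_g < alpha_level
    return dict(rejections=rejections, n_tables=n_tables,
                rate=rejections / n_tables)


def adaptive_alpha_recovery(
    n_reps: int = 100, n_segments: int = 2000, seed: int = 0
) -> dict:
    """Mean alpha point estimate over adaptive-regime replicates."""
    root = np.random.SeedSequence(seed).spawn(n_reps)
    alphas = []
    for r in range(n_reps):
        rec = simulate.simulate_segment_records(
            n_segments, **ADAPTIVE_RATES, seed=np.random.default_rng(root[r])
        )
        alphas.append(mk.alpha(mk.build_mk_table(rec)))
    return dict(mean_alpha=float(np.mean(alphas)), alpha_star=ALPHA_STAR,
                n_reps=n_reps)


def focal_selection_battery(seed: int = 0, n_boot: int = 100) -> pd.DataFrame:
    """Shuffle battery on a genome where selection hits only focal cores.

    Divergence is elevated (and the full adaptive regime applied) only at
    the planted focal-motif cores; every shuffled control motif therefore
    sees purely neutral sites, and the focal alpha should exceed all
    controls.
    """
    cfg = simulate.SimConfig(
        seed=seed,
        chrom_specs=(("chr2L", 600_000, "autosome"), ("chrX", 400_000, "X")),
        n_motifs=400,
        **ADAPTIVE_RATES,
    )
    genome, truth = simulate.simulate_genome(cfg)
    derived, blocks, _ = simulate.simulate_divergence(genome, truth, cfg)
    variants = simulate.simulate_polymorphism(genome, truth, cfg)
    return mk.shuffle_null_battery(
        genome, derived, BlockMap(blocks), variants,
        motifs=sorted(scan.shuffle_motifs(cfg.motif)), focal_motif=cfg.motif,
        n_boot=n_boot, seed=seed,
    )


def chip_design_study(seed: int = 0, n_perm: int = 5000) -> dict:
    """Replicated 3-factor ChIP design with a planted X affinity.

    Factors bind disjoint gene sets (so replicates cluster by factor) and
    one factor additionally gets 5-fold reads at every X-linked TSS.
    Returns the PC1-PC2 silhouette of factor labels, the X-vs-autosome
    permutation p for the boosted and an unboosted factor, and the
    boosted factor's p after permuting the genes' chromosome labels
    (negative control: the gene-to-chromosome association is destroyed,
    so no enrichment should remain).
    """
    cfg = simulate.SimConfig(
        seed=seed,
        chrom_specs=(("chr2L", 200_000, "autosome"), ("chrX", 150_000, "X")),
        n_genes=120,
        chip_enrichment=8.0,
    )
    genes = simulate.simulate_annotation(cfg)
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    gene_ids = [g.gene_id for g in genes]
    order = rng.permutation(gene_ids)
    bound = {f: list(order[30 * i: 30 * (i + 1)])
             for i, f in enumerate(cfg.chip_factors)}
    boosted, flat = cfg.chip_factors[1], cfg.chip_factors[0]
    reads, _ = simulate.simulate_chip(
        genes, bound, cfg, factor_chrom_fold={boosted: {"chrX": 5.0}}
    )
    meta = pd.DataFrame(
        {"factor": [f for f, _ in reads], "replicate": [r for _, r in reads]},
        index=[f"{f}_r{r}" for f, r in reads],
    )
    matrix = chip.normalize_signal(chip.tss_window_counts(
        {f"{f}_r{r}": df for (f, r), df in reads.items()}, genes, samples=meta
    ))
    _, silhouette = chip.pca_cluster_check(matrix)
    classes = {"chr2L": "autosome", "chrX": "X"}
    _, p_enrich = chip.chromosome_enrichment(matrix, genes, classes,
                                             n_perm=n_perm, seed=rng)
    # negative control: shuffle which chromosome each gene is labelled
    # with before rescoring the boosted factor
    import dataclasses as _dc

    shuffled_chroms = rng.permutation([g.chrom for g in genes])
    perm_genes = [_dc.replace(g, chrom=c) for g, c in zip(genes, shuffled_chroms)]
    _, p_perm = chip.chromosome_enrichment(matrix, perm_genes, classes,
                                           n_perm=n_perm, seed=rng)
    return dict(
        silhouette=silhouette,
        p_x_boosted=float(p_enrich[boosted]),
        p_x_flat=float(p_enrich[flat]),
        p_x_label_permuted=float(p_perm[boosted]),
    )


def phylo_type_i(
    n_runs: int = 500, n_sim: int = 199, alpha_level: float = 0.05, seed: int = 0
) -> dict:
    """Type-I error of the phylogenetic ANOVA under its own BM null."""
    root = np.random.SeedSequence(seed).spawn(n_runs)
    rejections = 0
    for r in range(n_runs):
        trait_rng, sim_rng = [np.random.default_rng(s) for s in root[r].spawn(2)]
        traits = simulate.simulate_bm_traits(
            phylo.FIXTURE_TREE_9, sigma2=1.0, seed=trait_rng
        )
        ts = phylo.SpeciesTraitSet(
            tree=phylo.FIXTURE_TREE_9, traits=traits,
            groups=dict(phylo.FIXTURE_GROUPS_9),
        )
        _, p = phylo.phyl_anova(ts, n_sim=n_sim, seed=sim_rng)
        rejections += p <= alpha_level
    return dict(rejections=rejections, n_runs=n_runs, rate=rejections / n_runs)


def star_tree_agreement(n_tips: int = 10, n_sim: int = 20_000, seed: int = 0) -> dict:
    """On a star tree the simulated null must match the ordinary ANOVA."""
    star = "(" + ",".join(f"t{i}:1" for i in range(n_tips)) + ");"
    rng = np.random.default_rng(seed)
    traits = {f"t{i}": float(rng.normal()) for i in range(n_tips)}
    groups = {f"t{i}": ("a" if i < n_tips // 2 else "b") for i in range(n_tips)}
    ts = phylo.SpeciesTraitSet(tree=star, traits=traits, groups=groups)
    f_obs, p_sim = phylo.phyl_anova(ts, n_sim=n_sim, seed=rng)
    vals = list(traits.values())
    _, p_ref = stats.f_oneway(vals[: n_tips // 2], vals[n_tips // 2:])
    return dict(p_sim=float(p_sim), p_ref=float(p_ref),
                gap=abs(float(p_sim) - float(p_ref)))
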