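"""End-to-end synthetic study: simulate -> scan -> map -> MK -> shuffle
battery -> ChIP comparison -> phylogenetic ANOVA, with a reproducibility
manifest.

Stages run in dependency order, write plain TSV/FASTA/VCF/GFF3/BED files
into the output directory, and record a SHA-256 digest of every output
in ``manifest.json``; re-running with the same config and seed
reproduces every digest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, chip, io, mk, orthomap, phylo, scan, simulate
from .annotation import exon_intervals, write_gff3


logger = logging.getLogger(__name__)


def load_config(path: str | Path) -> simulate.SimConfig:
    """Read a SimConfig from YAML (or TOML, by extension)."""
    path = Path(path)
    if path.suffix == ".toml":
        import tomllib

        raw = tomllib.loads(path.read_text())
    else:
        raw = yaml.safe_load(path.read_text())
    if "chrom_specs" in raw:
        raw["chrom_specs"] = [tuple(spec) for spec in raw["chrom_specs"]]
    return simulate.SimConfig(**raw)


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_full(
    config: simulate.SimConfig,
    outdir: str | Path,
    n_boot: int = 500,
    battery_n_boot: int = 100,
    n_perm: int = 500,
    n_sim_phylo: int = 500,
    run_battery: bool = True,
) -> dict:
    """Run the whole synthetic study; returns the manifest dict.

    Any stage failure propagates with the stage name in the log. The
    selection regime, genome sizes and replicate structure all come from
    ``config``; analysis Monte-Carlo sizes are arguments so a demo run
    stays fast.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files: dict[str, Path] = {}

    def stage(name: str):
        logger.info("stage %s", name)

    # --- simulate ---------------------------------------------------------
    stage("simulate_annotation")
    genes = simulate.simulate_annotation(config)
    files["genes.gff3"] = outdir / "genes.gff3"
    write_gff3(genes, files["genes.gff3"])

    stage("simulate_genome")
    genome, truth = simulate.simulate_genome(config, genes=genes)
    files["genome.fa"] = outdir / "genome.fa"
    genome.to_fasta(files["genome.fa"])
    files["truth_motifs.bed"] = outdir / "truth_motifs.bed"
    scan.write_bed(truth, files["truth_motifs.bed"])

    stage("simulate_divergence")
    derived, blocks, sub_log = simulate.simulate_divergence(genome, truth, config)
    files["genome_derived.fa"] = outdir / "genome_derived.fa"
    derived.to_fasta(files["genome_derived.fa"])
    files["blocks.tsv"] = outdir / "blocks.tsv"
    io.write_blocks(blocks, files["blocks.tsv"])
    files["substitutions.tsv"] = outdir / "substitutions.tsv"
    sub_log.to_csv(files["substitutions.tsv"], sep="\t", index=False)

    stage("simulate_polymorphism")
    variants = simulate.simulate_polymorphism(genome, truth, config)
    files["snps.vcf"] = outdir / "snps.vcf"
    io.write_vcf(variants, files["snps.vcf"], genome.lengths())

    # --- scan -------------------------------------------------------------
    stage("scan_motif")
    instances = scan.scan_motif(genome, config.motif)
    files["instances.bed"] = outdir / "instances.bed"
    scan.write_bed(instances, files["instances.bed"])
    freq = scan.genome_frequency(instances, genome)
    freq_df = pd.DataFrame(
        [dict(genome_id=freq.genome_id, count=freq.count, genome_bp=freq.genome_bp,
              density_per_mb=freq.density_per_mb, **freq.by_class)]
    )
    files["motif_frequency.tsv"] = outdir / "motif_frequency.tsv"
    freq_df.to_csv(files["motif_frequency.tsv"], sep="\t", index=False)

    # --- map + MK ---------------------------------------------------------
    stage("map_segments")
    block_map = orthomap.BlockMap(blocks)
    segments = orthomap.build_segments(instances, genome)
    pairs = orthomap.map_segments(segments, block_map, genome, derived)
    status_counts = pd.Series([p.status for p in pairs]).value_counts()
    files["mapping_summary.tsv"] = outdir / "mapping_summary.tsv"
    status_counts.rename_axis("status").rename("n").to_frame().to_csv(
        files["mapping_summary.tsv"], sep="\t")

    stage("classify_sites")
    records = orthomap.classify_pairs(pairs, variants)
    exons = exon_intervals(genes)
    records = mk.annotate_site_records(records, genome.classes, exons)
    files["site_records.tsv"] = outdir / "site_records.tsv"
    records.to_csv(files["site_records.tsv"], sep="\t", index=False)

    stage("mk_alpha")
    rows = []
    est = mk.bootstrap_alpha(records, n_boot=n_boot, seed=config.seed)
    rows.append(dict(stratum="all", **dataclasses.asdict(est)))
    for col, value in (("chrom_class", "X"), ("chrom_class", "autosome"),
                       ("location", "exonic"), ("location", "intergenic")):
        sub = records[records[col] == value]
        if sub["segment"].nunique() >= 2:
            try:
                est_s = mk.bootstrap_alpha(sub, n_boot=n_boot, seed=config.seed)
                rows.append(dict(stratum=value, **dataclasses.asdict(est_s)))
            except (ValueError, mk.UndefinedAlphaError) as exc:
                logger.info("stratum %s: alpha unavailable (%s)", value, exc)
    mk_summary = pd.DataFrame(rows)
    files["mk_summary.tsv"] = outdir / "mk_summary.tsv"
    mk_summary.to_csv(files["mk_summary.tsv"], sep="\t", index=False)

    if run_battery:
        stage("shuffle_null_battery")
        battery = mk.shuffle_null_battery(
            genome, derived, block_map, variants,
            motifs=sorted(scan.shuffle_motifs(config.motif)),
            focal_motif=config.motif, n_boot=battery_n_boot, seed=config.seed,
        )
        files["shuffle_battery.tsv"] = outdir / "shuffle_battery.tsv"
        battery.assign(focal_exceeds_all=battery.attrs["focal_exceeds_all"]).to_csv(
            files["shuffle_battery.tsv"], sep="\t", index=False)

    # --- ChIP -------------------------------------------------------------
    stage("chip")
    rng = config.rng("chip")
    gene_ids = [g.gene_id for g in genes]
    n_bound = max(1, len(gene_ids) // 5)
    bound = {
        f: list(rng.choice(gene_ids, size=n_bound, replace=False))
        for f in config.chip_factors
    }
    reads, peaks = simulate.simulate_chip(genes, bound, config)
    sample_ids = [f"{f}_r{r}" for f, r in reads]
    meta = pd.DataFrame(
        {"factor": [f for f, _ in reads], "replicate": [r for _, r in reads]},
        index=sample_ids,
    )
    matrix = chip.tss_window_counts(
        {f"{f}_r{r}": df for (f, r), df in reads.items()}, genes,
        samples=meta, chrom_lengths=genome.lengths(),
    )
    norm = chip.normalize_signal(matrix)
    files["signal_matrix.tsv"] = outdir / "signal_matrix.tsv"
    norm.values.to_csv(files["signal_matrix.tsv"], sep="\t")
    coords, silhouette = chip.pca_cluster_check(norm)
    medians, p_enrich = chip.chromosome_enrichment(
        norm, genes, genome.classes, n_perm=n_perm, seed=config.seed)
    files["chromosome_medians.tsv"] = outdir / "chromosome_medians.tsv"
    medians.to_csv(files["chromosome_medians.tsv"], sep="\t")
    f0 = config.chip_factors[0]
    conservative = chip.intersect_replicate_peaks(
        chip.peaks_from_frame(peaks[(f0, 1)]), chip.peaks_from_frame(peaks[(f0, 2)])
    ) if config.n_replicates >= 2 else []
    bound_called = chip.bound_genes(conservative, genes)
    chip_summary = pd.DataFrame(
        [dict(silhouette=silhouette, n_conservative_peaks=len(conservative),
              n_bound_genes=len(bound_called),
              **{f"p_x_enrichment_{f}": p for f, p in p_enrich.items()})]
    )
    files["chip_summary.tsv"] = outdir / "chip_summary.tsv"
    chip_summary.to_csv(files["chip_summary.tsv"], sep="\t", index=False)

    # --- phylogenetic ANOVA ----------------------------------------------
    stage("phylo_anova")
    with_zeus = [t for t, g in phylo.FIXTURE_GROUPS_9.items() if g == "with_Zeus"]
    traits = simulate.simulate_bm_traits(
        phylo.FIXTURE_TREE_9, sigma2=1.0, group_effect=-2.0,
        effect_tips=with_zeus, seed=config.rng("traits"),
    )
    trait_set = phylo.SpeciesTraitSet(
        tree=phylo.FIXTURE_TREE_9, traits=traits, groups=dict(phylo.FIXTURE_GROUPS_9)
    )
    f_obs, p_phylo = phylo.phyl_anova(trait_set, n_sim=n_sim_phylo, seed=config.seed)
    files["phylo_anova.tsv"] = outdir / "phylo_anova.tsv"
    pd.DataFrame([dict(F_obs=f_obs, p_phylo=p_phylo,
                       sigma2_hat=phylo.bm_rate_estimate(trait_set))]).to_csv(
        files["phylo_anova.tsv"], sep="\t", index=False)

    # --- manifest ---------------------------------------------------------
    manifest = dict(
        motifmk_version=__version__,
        seed=config.seed,
        config={
            k: (list(map(list, v)) if k == "chrom_specs" else v)
            for k, v in dataclasses.asdict(config).items()
            if not callable(v)
        },
        digests={name: _digest(path) for name, path in sorted(files.items())},
    )
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
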