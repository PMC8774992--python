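"""Synthetic study generator: genomes with planted motifs, divergence and
polymorphism with distinct core/flank rates, gene models, TSS-enriched ChIP
reads with replicate structure, and Brownian-motion trait evolution on a tree.

Every generator draws from a named substream spawned from the single
``SimConfig.seed``, so the same seed and config reproduce byte-identical
output files, and adding a new generator does not perturb existing ones.

The default substitution/polymorphism regime plants positive selection at
motif cores: per-site divergence probability ``mu_core`` = 0.2 versus
``mu_flank`` = 0.05 with equal per-site polymorphism probabilities
(``theta`` = 0.05), for which the expected adaptive fraction is

    alpha* = 1 - (mu_flank * theta_core) / (mu_core * theta_flank) = 0.75.

Set ``mu_core == mu_flank`` and ``theta_core == theta_flank`` for a fully
neutral genome.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

from .annotation import GeneModel, exon_intervals
from .genome import CHROM_CLASSES, GenomeSequence, revcomp
from .scan import MotifInstance

BASES = np.array(list("ACGT"))

#: Named substreams in spawn order; append-only so streams stay stable.
_STREAMS = ("annotation", "genome", "divergence", "polymorphism", "chip", "traits")

DEFAULT_CHROMS = (
    ("chr2L", 200_000, "autosome"),
    ("chrX", 150_000, "X"),
    ("chr4", 50_000, "dot"),
    ("chrU", 30_000, "unassembled"),
)


def neutral_maf_spectrum(n_chromosomes: int = 200) -> Callable:
    """Folded neutral site-frequency spectrum for a resequencing panel.

    Minor allele frequencies i/n (i = 1 .. n/2) weighted by the folded
    neutral expectation 1/i + 1/(n-i); n = 200 approximates a DGRP-sized
    panel.
    """
    i = np.arange(1, n_chromosomes // 2 + 1)
    weights = 1.0 / i + 1.0 / (n_chromosomes - i)
    weights[-1] /= 2  # i = n/2 folds onto itself
    probs = weights / weights.sum()
    freqs = i / n_chromosomes

    def sample(rng: np.random.Generator, size: int) -> np.ndarray:
        return rng.choice(freqs, size=size, p=probs)

    return sample


@dataclass
class SimConfig:
    """Parameters of the synthetic study.

    Rates are per-site probabilities over the simulated species split
    (``mu_*`` for fixed divergence, ``theta_*`` for segregating
    polymorphism), applied at motif-core versus all other (flank) sites.
    """

    seed: int = 0
    chrom_specs: Sequence[tuple[str, int, str]] = DEFAULT_CHROMS
    gc_content: float = 0.42
    n_motifs: int = 300
    motif: str = "ACTGCTT"
    exon_proximity_bias: float = 0.0
    chrom_weights: Mapping[str, float] | None = None
    mu_flank: float = 0.05
    mu_core: float = 0.2
    theta_flank: float = 0.05
    theta_core: float = 0.05
    maf_spectrum: float | Callable | None = None
    indel_fraction: float = 0.0
    n_genes: int = 100
    chip_factors: Sequence[str] = ("Dmel_Zeus", "Dsim_Zeus", "Dyak_Caf40")
    n_replicates: int = 4
    chip_enrichment: float = 8.0
    chip_background_reads: int = 20_000

    def __post_init__(self) -> None:
        if not self.chrom_specs:
            raise ValueError("need at least one chromosome")
        for name, length, cls in self.chrom_specs:
            if length <= 0:
                raise ValueError(f"chromosome {name} has non-positive length")
            if cls not in CHROM_CLASSES:
                raise ValueError(f"unknown chromosome class {cls!r}")
        for attr in (
            "gc_content", "exon_proximity_bias", "mu_flank", "mu_core",
            "theta_flank", "theta_core", "indel_fraction",
        ):
            v = getattr(self, attr)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{attr}={v} outside [0, 1]")
        self.motif = self.motif.upper()
        if not self.motif or set(self.motif) - set("ACGT"):
            raise ValueError("motif must be non-empty over ACGT")
        if self.n_motifs < 0 or self.n_genes < 0 or self.n_replicates < 1:
            raise ValueError("counts must be non-negative (replicates >= 1)")
        if self.chip_enrichment < 0 or self.chip_background_reads < 0:
            raise ValueError("ChIP parameters must be non-negative")

    def rng(self, stream: str) -> np.random.Generator:
        """Deterministic per-component substream of the master seed."""
        children = np.random.SeedSequence(self.seed).spawn(len(_STREAMS))
        return np.random.default_rng(children[_STREAMS.index(stream)])

    def sample_maf(self, rng: np.random.Generator, size: int) -> np.ndarray:
        spec = self.maf_spectrum
        if spec is None:
            spec = neutral_maf_spectrum()
        if callable(spec):
            mafs = np.asarray(spec(rng, size), dtype=float)
        else:
            mafs = np.full(size, float(spec))
        if np.any((mafs <= 0) | (mafs > 0.5)):
            raise ValueError("MAF spectrum must produce values in (0, 0.5]")
        return mafs

    def replace(self, **kwargs) -> "SimConfig":
        return dataclasses.replace(self, **kwargs)


def _random_sequence(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(4, size=length, p=p).astype(np.int8)


def simulate_annotation(config: SimConfig) -> list[GeneModel]:
    """Non-overlapping genes with 1-3 exons each, placed genome-wide.

    Genes are laid out on evenly spaced non-overlapping slots allocated
    across chromosomes in proportion to length, each with a random
    strand; the TSS is the strand-respecting 5' end.
    """
    rng = config.rng("annotation")
    if config.n_genes == 0:
        return []
    lengths = {name: length for name, length, _ in config.chrom_specs}
    total = sum(lengths.values())
    # allocate gene slots per chromosome in proportion to length
    alloc = {name: int(round(config.n_genes * l / total)) for name, l in lengths.items()}
    drift = config.n_genes - sum(alloc.values())
    alloc[max(lengths, key=lengths.get)] += drift
    gene_len = 1000
    genes: list[GeneModel] = []
    for name, l in lengths.items():
        n = alloc[name]
        if n == 0:
            continue
        slot = l // n
        if slot < gene_len * 2:
            raise ValueError(
                f"genome too small for {config.n_genes} genes "
                f"(chromosome {name}: slot {slot} bp < {gene_len * 2} bp)"
            )
        for k in range(n):
            offset = int(rng.integers(0, slot - gene_len))
            start = k * slot + offset
            end = start + gene_len
            strand = "+" if rng.random() < 0.5 else "-"
            n_exons = int(rng.integers(1, 4))
            bounds = np.sort(rng.choice(np.arange(1, 10), size=2 * n_exons - 2, replace=False)) * (gene_len // 10)
            edges = [0, *bounds.tolist(), gene_len]
            exons = tuple(
                (start + edges[2 * i], start + edges[2 * i + 1]) for i in range(n_exons)
            )
            genes.append(GeneModel(f"g{len(genes):04d}", name, start, end, strand, exons))
    genes.sort(key=lambda g: (g.chrom, g.start))
    return genes


def simulate_genome(
    config: SimConfig, genes: Sequence[GeneModel] | None = None
) -> tuple[GenomeSequence, list[MotifInstance]]:
    """Random genome at the requested GC with planted motif copies.

    Exactly ``n_motifs`` non-overlapping copies of the motif (forward or
    reverse complement, 50/50) are written into the sequence; chance
    background occurrences may also arise and are not in the returned
    truth set. With ``exon_proximity_bias`` > 0 that fraction of plants
    is constrained to lie within 1 kb of an exon of ``genes``.
    """
    rng = config.rng("genome")
    m = len(config.motif)
    lengths = {name: length for name, length, _ in config.chrom_specs}
    classes = {name: cls for name, length, cls in config.chrom_specs}
    if m > min(lengths.values()):
        raise ValueError("motif longer than the shortest chromosome")
    if config.n_motifs * m > sum(lengths.values()) // 2:
        raise ValueError("infeasible placement: too many motifs for genome size")
    if config.exon_proximity_bias > 0 and not genes:
        raise ValueError("exon_proximity_bias > 0 requires gene models")

    seqs = {name: _random_sequence(rng, l, config.gc_content) for name, l in lengths.items()}

    names = list(lengths)
    if config.chrom_weights is None:
        weights = np.array([lengths[n] for n in names], dtype=float)
    else:
        weights = np.array([config.chrom_weights.get(n, 0.0) for n in names], dtype=float)
    if weights.sum() <= 0:
        raise ValueError("chromosome placement weights sum to zero")
    weights = weights / weights.sum()

    # candidate windows near exons, for the proximity-biased plants
    exon_windows: list[tuple[str, int, int]] = []
    if genes:
        for chrom, ivs in exon_intervals(genes).items():
            if chrom not in lengths:
                continue
            for s, e in ivs:
                lo = max(0, s - 1000)
                hi = min(lengths[chrom], e + 1000)
                if hi - lo >= m:
                    exon_windows.append((chrom, lo, hi))

    occupied: dict[str, list[tuple[int, int]]] = {name: [] for name in names}

    def overlaps(chrom: str, start: int, end: int) -> bool:
        return any(start < e and s < end for s, e in occupied[chrom])

    truth: list[MotifInstance] = []
    motif_arr = {
        "+": np.array(["ACGT".index(b) for b in config.motif], dtype=np.int8),
        "-": np.array(["ACGT".index(b) for b in revcomp(config.motif)], dtype=np.int8),
    }
    max_attempts = 200 * max(1, config.n_motifs)
    attempts = 0
    while len(truth) < config.n_motifs:
        attempts += 1
        if attempts > max_attempts:
            raise ValueError("infeasible placement: could not place all motifs")
        near_exon = config.exon_proximity_bias > 0 and rng.random() < config.exon_proximity_bias
        if near_exon:
            chrom, lo, hi = exon_windows[int(rng.integers(len(exon_windows)))]
            start = int(rng.integers(lo, hi - m + 1))
        else:
            chrom = names[int(rng.choice(len(names), p=weights))]
            start = int(rng.integers(0, lengths[chrom] - m + 1))
        end = start + m
        if overlaps(chrom, start, end):
            continue
        strand = "+" if rng.random() < 0.5 else "-"
        seqs[chrom][start:end] = motif_arr[strand]
        occupied[chrom].append((start, end))
        placed = config.motif if strand == "+" else revcomp(config.motif)
        truth.append(MotifInstance(chrom, start, end, strand, placed))

    chroms = {name: "".join(BASES[s]) for name, s in seqs.items()}
    truth.sort()
    return GenomeSequence(chroms, classes), truth


def _core_mask(genome: GenomeSequence, truth: Sequence[MotifInstance]) -> dict[str, np.ndarray]:
    masks = {name: np.zeros(len(seq), dtype=bool) for name, seq in genome.chroms.items()}
    for inst in truth:
        masks[inst.chrom][inst.start:inst.end] = True
    return masks


def simulate_divergence(
    genome: GenomeSequence,
    truth: Sequence[MotifInstance],
    config: SimConfig,
    block_shuffle: int = 0,
    block_identity_jitter: float = 0.0,
) -> tuple[GenomeSequence, pd.DataFrame, pd.DataFrame]:
    """Independently mutate each site; cores of truth motifs at ``mu_core``.

    Returns the diverged genome, an alignment BlockMap table (identity
    lift by default: one full-length block per chromosome at identity
    1.0), and a log of every substitution with its site class. With
    ``block_shuffle`` = k > 0 each chromosome is fragmented into k blocks
    whose identities are jittered downward by up to
    ``block_identity_jitter``, to exercise minMatch failures.
    """
    rng = config.rng("divergence")
    masks = _core_mask(genome, truth)
    derived: dict[str, str] = {}
    log_rows = []
    for chrom, seq in genome.chroms.items():
        arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
        idx = {ord(b): i for i, b in enumerate("ACGT")}
        p = np.where(masks[chrom], config.mu_core, config.mu_flank)
        hit = rng.random(len(arr)) < p
        sites = np.flatnonzero(hit)
        for pos in sites:
            ref = chr(arr[pos])
            if ref not in "ACGT":
                continue
            alt = "ACGT"[(idx[arr[pos]] + int(rng.integers(1, 4))) % 4]
            arr[pos] = ord(alt)
            log_rows.append(
                dict(chrom=chrom, pos=int(pos), ref=ref, alt=alt,
                     site_class="core" if masks[chrom][pos] else "flank")
            )
        derived[chrom] = arr.tobytes().decode()

    block_rows = []
    for chrom, seq in genome.chroms.items():
        n = max(1, block_shuffle)
        edges = np.linspace(0, len(seq), n + 1, dtype=int)
        for s, e in zip(edges[:-1], edges[1:]):
            if e <= s:
                continue
            ident = 1.0
            if block_shuffle and block_identity_jitter > 0:
                ident = 1.0 - float(rng.random()) * block_identity_jitter
            block_rows.append(
                dict(src_chrom=chrom, src_start=int(s), src_end=int(e),
                     dst_chrom=chrom, dst_start=int(s), dst_end=int(e),
                     dst_strand="+", identity=ident)
            )
    blocks = pd.DataFrame(block_rows)
    log = pd.DataFrame(log_rows, columns=["chrom", "pos", "ref", "alt", "site_class"])
    return GenomeSequence(derived, dict(genome.classes)), blocks, log


def simulate_polymorphism(
    genome: GenomeSequence,
    truth: Sequence[MotifInstance],
    config: SimConfig,
) -> pd.DataFrame:
    """Segregating biallelic SNPs with per-class rates and a MAF spectrum.

    SNPs land at per-site probability ``theta_core`` on truth-motif cores
    and ``theta_flank`` elsewhere; each SNP's minor allele frequency is
    drawn from the configured spectrum. With ``indel_fraction`` > 0 that
    fraction of variants is emitted as 2-bp deletions for sensitivity
    runs. Returns a variant table (columns chrom, pos [0-based], ref,
    alt, af, is_snp) writable as VCF via :func:`motifmk.io.write_vcf`.
    """
    rng = config.rng("polymorphism")
    masks = _core_mask(genome, truth)
    rows = []
    for chrom, seq in genome.chroms.items():
        p = np.where(masks[chrom], config.theta_core, config.theta_flank)
        sites = np.flatnonzero(rng.random(len(seq)) < p)
        if sites.size == 0:
            continue
        mafs = config.sample_maf(rng, sites.size)
        for pos, maf in zip(sites, mafs):
            ref = seq[pos]
            if ref not in "ACGT":
                continue
            is_snp = rng.random() >= config.indel_fraction
            if is_snp:
                alt = "ACGT"[("ACGT".index(ref) + int(rng.integers(1, 4))) % 4]
            else:
                if pos + 2 > len(seq):
                    continue
                ref = seq[pos : pos + 2]
                alt = ref[0]
            af = float(maf) if rng.random() < 0.5 else float(1 - maf)
            rows.append(dict(chrom=chrom, pos=int(pos), ref=ref, alt=alt,
                             af=af, is_snp=bool(is_snp)))
    return pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "af", "is_snp"])


def simulate_chip(
    genes: Sequence[GeneModel],
    bound: Mapping[str, Sequence[str]] | Sequence[str],
    config: SimConfig,
    chrom_lengths: Mapping[str, int] | None = None,
    half_width: int = 350,
    factor_chrom_fold: Mapping[str, Mapping[str, float]] | None = None,
    factor_effect_sd: float = 0.5,
    n_spurious_peaks: int = 5,
) -> tuple[dict[tuple[str, int], pd.DataFrame], dict[tuple[str, int], pd.DataFrame]]:
    """Per-replicate ChIP read positions and narrowPeak calls.

    Background reads fall uniformly on the genome; each bound gene
    receives ``chip_enrichment``-fold the expected background count
    within +-``half_width`` bp of its TSS, modulated by a per-
    (factor, gene) log-normal binding effect (sd ``factor_effect_sd``)
    shared across replicates so replicates of a factor cluster together.
    ``factor_chrom_fold`` plants a chromosome-wide affinity: every gene
    on a named chromosome gets fold-times extra TSS-window reads for
    that factor (e.g. a planted X enrichment). Peaks are emitted at every
    bound TSS in every replicate, plus ``n_spurious_peaks`` random
    replicate-specific peaks that replicate intersection should remove.

    Returns ``(reads, peaks)`` keyed by (factor, replicate); reads have
    columns (chrom, pos), peaks narrowPeak-style columns.
    """
    rng = config.rng("chip")
    if chrom_lengths is None:
        chrom_lengths = {name: length for name, length, _ in config.chrom_specs}
    names = list(chrom_lengths)
    lens = np.array([chrom_lengths[n] for n in names], dtype=float)
    genome_bp = lens.sum()
    if not isinstance(bound, Mapping):
        bound = {f: list(bound) for f in config.chip_factors}
    gene_by_id = {g.gene_id: g for g in genes}
    window_bp = 2 * half_width + 1
    bg_rate = config.chip_background_reads / genome_bp

    reads: dict[tuple[str, int], pd.DataFrame] = {}
    peaks: dict[tuple[str, int], pd.DataFrame] = {}
    for factor in config.chip_factors:
        bound_ids = [g for g in bound.get(factor, []) if g in gene_by_id]
        effects = np.exp(rng.normal(0.0, factor_effect_sd, size=len(bound_ids)))
        chrom_fold = (factor_chrom_fold or {}).get(factor, {})
        for rep in range(1, config.n_replicates + 1):
            chrom_idx = rng.choice(len(names), size=config.chip_background_reads,
                                   p=lens / genome_bp)
            pos = (rng.random(config.chip_background_reads) * lens[chrom_idx]).astype(int)
            rows = [pd.DataFrame({"chrom": np.array(names)[chrom_idx], "pos": pos})]
            peak_rows = []
            for gid, eff in zip(bound_ids, effects):
                g = gene_by_id[gid]
                lo = max(0, g.tss - half_width)
                hi = min(chrom_lengths[g.chrom], g.tss + half_width + 1)
                lam = (config.chip_enrichment - 1) * bg_rate * window_bp * eff
                n_extra = rng.poisson(max(lam, 0.0))
                if n_extra:
                    rows.append(pd.DataFrame({
                        "chrom": [g.chrom] * n_extra,
                        "pos": rng.integers(lo, hi, size=n_extra),
                    }))
                peak_rows.append(dict(chrom=g.chrom, start=lo, end=hi,
                                      name=f"{factor}_r{rep}_{gid}",
                                      score=1000, strand=".",
                                      signalValue=float(config.chip_enrichment),
                                      pValue=-1.0, qValue=-1.0,
                                      peak=(hi - lo) // 2))
            for g in genes:  # chromosome-wide affinity boost
                fold = chrom_fold.get(g.chrom, 1.0)
                if fold == 1.0:
                    continue
                lo = max(0, g.tss - half_width)
                hi = min(chrom_lengths[g.chrom], g.tss + half_width + 1)
                n_extra = rng.poisson(max((fold - 1.0) * bg_rate * window_bp, 0.0))
                if n_extra:
                    rows.append(pd.DataFrame({
                        "chrom": [g.chrom] * n_extra,
                        "pos": rng.integers(lo, hi, size=n_extra),
                    }))
            for _ in range(n_spurious_peaks):
                ci = int(rng.choice(len(names), p=lens / genome_bp))
                s = int(rng.integers(0, max(1, chrom_lengths[names[ci]] - 200)))
                peak_rows.append(dict(chrom=names[ci], start=s, end=s + 200,
                                      name=f"{factor}_r{rep}_spurious", score=100,
                                      strand=".", signalValue=1.0, pValue=-1.0,
                                      qValue=-1.0, peak=100))
            rd = pd.concat(rows, ignore_index=True).sort_values(
                ["chrom", "pos"], ignore_index=True)
            reads[(factor, rep)] = rd
            peaks[(factor, rep)] = pd.DataFrame(peak_rows).sort_values(
                ["chrom", "start"], ignore_index=True)
    return reads, peaks


def simulate_bm_traits(
    tree: dendropy.Tree | str,
    sigma2: float,
    group_effect: float = 0.0,
    effect_tips: Sequence[str] = (),
    seed: int | np.random.Generator = 0,
    root_value: float = 0.0,
) -> dict[str, float]:
    """One-rate Brownian-motion trait values at the tips of a tree.

    Each edge contributes an independent Gaussian increment of variance
    ``sigma2 * branch_length``; tips named in ``effect_tips``
    additionally receive ``group_effect``.
    """
    if sigma2 < 0:
        raise ValueError("sigma2 must be >= 0")
    if isinstance(tree, str):
        tree = dendropy.Tree.get(data=tree, schema="newick")
    rng = np.random.default_rng(seed)
    values: dict[int, float] = {id(tree.seed_node): root_value}
    out: dict[str, float] = {}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            v = root_value
        else:
            bl = node.edge.length or 0.0
            v = values[id(node.parent_node)] + rng.normal(0.0, math.sqrt(sigma2 * bl))
        values[id(node)] = v
        if node.is_leaf():
            name = node.taxon.label
            out[name] = v + (group_effect if name in effect_tips else 0.0)
    return out


def simulate_segment_records(
    n_segments: int,
    mu_core: float,
    mu_flank: float,
    theta_core: float,
    theta_flank: float,
    motif_len: int = 7,
    flank_bp: int = 7,
    chrom: str = "chr2L",
    seed: int | np.random.Generator = 0,
    segment_offset: int = 0,
) -> pd.DataFrame:
    """Site records drawn directly at the segment level.

    Each of ``n_segments`` segments has ``motif_len`` core sites flanked
    by ``flank_bp`` sites on each side; every site is independently
    divergent with its class's ``mu`` and polymorphic with its class's
    ``theta``, and a site that is both counts as polymorphic only (the
    same convention as the genome pipeline's site classifier). The
    output has the same schema as
    :func:`motifmk.orthomap.classify_segment_sites`, so the MK
    machinery runs on it unchanged — this is the desk-scale generative
    model used for calibration and rate-recovery studies.
    """
    rng = np.random.default_rng(seed)
    for name, v in dict(mu_core=mu_core, mu_flank=mu_flank,
                        theta_core=theta_core, theta_flank=theta_flank).items():
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name}={v} outside [0, 1]")
    seg_len = motif_len + 2 * flank_bp
    classes = np.array(
        ["flank"] * flank_bp + ["core"] * motif_len + ["flank"] * flank_bp
    )
    is_core = classes == "core"
    mu = np.where(is_core, mu_core, mu_flank)
    theta = np.where(is_core, theta_core, theta_flank)
    div = rng.random((n_segments, seg_len)) < mu
    poly = rng.random((n_segments, seg_len)) < theta
    fixed = div & ~poly  # polymorphic-and-divergent counts as polymorphic
    seg_ids = np.repeat(np.arange(segment_offset, segment_offset + n_segments), seg_len)
    positions = (
        np.arange(n_segments)[:, None] * (seg_len + 10) + np.arange(seg_len)
    ).ravel()
    return pd.DataFrame(
        dict(
            segment=seg_ids,
            chrom=chrom,
            pos=positions,
            site_class=np.tile(classes, n_segments),
            fixed_diff=fixed.ravel().astype(int),
            polymorphic=poly.ravel().astype(int),
        )
    )
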