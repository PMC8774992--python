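"""Genome-wide scanning of a short core motif and its distribution statistics.

The scan is exact-match on both strands: a reverse-complement occurrence
is a genomic interval whose forward-strand bases equal the reverse
complement of the motif, reported with strand '-'. Overlapping matches
are all reported, and positions containing N never match. Downstream
statistics cover genome-wide frequency (count and density per Mb, with a
per-chromosome-class breakdown), per-gene promoter counts in a
strand-aware 500-bp upstream window, the fraction of motif instances
within 1 kb of an annotated exon, and a downsampling-based two-genome
comparison of that fraction that reports the most conservative (maximum)
Fisher p over iterated downsamplings.
"""

from __future__ import annotations

import bisect
import itertools
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import GeneModel
from .genome import GenomeSequence, revcomp

logger = logging.getLogger(__name__)

#: The 7-bp core consensus (CAZAM) bound by Caf40/Zeus-family proteins.
CORE_MOTIF = "ACTGCTT"


@dataclass(frozen=True, order=True)
class MotifInstance:
    """A strand-aware exact occurrence of the core motif.

    ``seq`` holds genomic (forward-strand) bases: it equals the motif on
    strand '+' and the motif's reverse complement on strand '-'.
    """

    chrom: str
    start: int
    end: int
    strand: str
    seq: str

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        if self.end - self.start != len(self.seq):
            raise ValueError("interval length != sequence length")


@dataclass(frozen=True)
class MotifFrequencyRecord:
    """Raw motif count and genome-size-corrected density for one genome."""

    genome_id: str
    count: int
    genome_bp: int
    density_per_mb: float
    by_class: dict[str, int]


def _validate_motif(motif: str) -> str:
    motif = motif.upper()
    if not motif or set(motif) - set("ACGT"):
        raise ValueError(f"motif must be a non-empty string over ACGT, got {motif!r}")
    return motif


def _find_all(haystack: str, needle: str) -> Iterable[int]:
    i = haystack.find(needle)
    while i != -1:
        yield i
        i = haystack.find(needle, i + 1)


def scan_motif(genome: GenomeSequence, motif: str = CORE_MOTIF) -> list[MotifInstance]:
    """All exact occurrences of ``motif`` and its reverse complement.

    Returns instances sorted by (chrom, start, strand); '+' sorts before
    '-'. A palindromic motif is reported once per strand at each site.
    """
    motif = _validate_motif(motif)
    rc = revcomp(motif)
    out: list[MotifInstance] = []
    for chrom, seq in genome.chroms.items():
        for start in _find_all(seq, motif):
            out.append(MotifInstance(chrom, start, start + len(motif), "+", motif))
        for start in _find_all(seq, rc):
            out.append(MotifInstance(chrom, start, start + len(motif), "-", rc))
    out.sort()
    return out


def genome_frequency(
    instances: Sequence[MotifInstance],
    genome: GenomeSequence,
    genome_id: str = "genome",
) -> MotifFrequencyRecord:
    """Raw count and per-Mb density, with a per-chromosome-class breakdown."""
    size = len(genome)
    if size == 0:
        raise ValueError("zero-length genome")
    by_class = {cls: 0 for cls in set(genome.classes.values())}
    for inst in instances:
        by_class[genome.classes[inst.chrom]] += 1
    count = len(instances)
    return MotifFrequencyRecord(
        genome_id=genome_id,
        count=count,
        genome_bp=size,
        density_per_mb=count / (size / 1e6),
        by_class=by_class,
    )


def shuffle_motifs(motif: str) -> set[str]:
    """All distinct two-position transpositions of ``motif``.

    Every unordered pair of positions is swapped once; products equal to
    the motif itself, or to its reverse complement (which matches the
    same genomic sites), are excluded. For the 7-bp core ACTGCTT this
    yields 17 distinct control motifs.
    """
    motif = _validate_motif(motif)
    if len(motif) < 2:
        raise ValueError("motif must have length >= 2")
    excluded = {motif, revcomp(motif)}
    out: set[str] = set()
    chars = list(motif)
    for i, j in itertools.combinations(range(len(chars)), 2):
        swapped = chars.copy()
        swapped[i], swapped[j] = swapped[j], swapped[i]
        candidate = "".join(swapped)
        if candidate not in excluded:
            out.add(candidate)
    return out


def promoter_motif_count(
    genes: Sequence[GeneModel],
    instances: Sequence[MotifInstance],
    genome: GenomeSequence,
    upstream_bp: int = 500,
) -> pd.Series:
    """Motif instances fully inside each gene's upstream promoter window.

    The promoter is the strand-aware ``upstream_bp`` window immediately
    5' of the TSS (500 bp by default), truncated at chromosome edges.
    Instances on either strand count. Genes whose span falls off their
    chromosome are skipped with a warning.
    """
    if upstream_bp <= 0:
        raise ValueError("upstream_bp must be > 0")
    lengths = genome.lengths()
    starts: dict[str, list[int]] = {}
    by_chrom: dict[str, list[MotifInstance]] = {}
    for inst in instances:
        by_chrom.setdefault(inst.chrom, []).append(inst)
    for chrom, insts in by_chrom.items():
        insts.sort(key=lambda x: x.start)
        starts[chrom] = [x.start for x in insts]

    counts: dict[str, int] = {}
    for gene in genes:
        if gene.chrom not in lengths or gene.end > lengths[gene.chrom]:
            logger.warning("gene %s lies off chromosome %s; skipped", gene.gene_id, gene.chrom)
            continue
        if gene.strand == "+":
            win_start, win_end = max(0, gene.tss - upstream_bp), gene.tss
        else:
            win_start = gene.tss + 1
            win_end = min(lengths[gene.chrom], gene.tss + 1 + upstream_bp)
        n = 0
        chrom_starts = starts.get(gene.chrom, [])
        lo = bisect.bisect_left(chrom_starts, win_start)
        for inst in by_chrom.get(gene.chrom, [])[lo:]:
            if inst.start >= win_end:
                break
            if inst.start >= win_start and inst.end <= win_end:
                n += 1
        counts[gene.gene_id] = n
    return pd.Series(counts, dtype=int, name="promoter_motifs")


def _min_distances(
    instances: Sequence[MotifInstance],
    exons: Mapping[str, Sequence[tuple[int, int]]],
) -> np.ndarray:
    """Distance in bp from each instance to its nearest exon (inf if none).

    Overlap counts as distance 0; otherwise the gap between the closest
    half-open interval ends.
    """
    sorted_exons = {
        chrom: sorted(ivs) for chrom, ivs in exons.items() if len(ivs) > 0
    }
    ex_starts = {c: [s for s, _ in ivs] for c, ivs in sorted_exons.items()}
    # running maximum of ends handles contained intervals
    ex_maxend = {}
    for c, ivs in sorted_exons.items():
        maxend = []
        cur = 0
        for _, e in ivs:
            cur = max(cur, e)
            maxend.append(cur)
        ex_maxend[c] = maxend

    dists = np.full(len(instances), np.inf)
    for k, inst in enumerate(instances):
        ivs = sorted_exons.get(inst.chrom)
        if not ivs:
            continue
        i = bisect.bisect_right(ex_starts[inst.chrom], inst.end - 1)
        best = np.inf
        if i < len(ivs):  # nearest exon starting at/after the instance end
            best = min(best, max(0, ivs[i][0] - inst.end))
        if i > 0:  # exons starting before: gap from the running max end
            prev_end = ex_maxend[inst.chrom][i - 1]
            best = min(best, max(0, inst.start - prev_end))
        dists[k] = best
    return dists


def exon_proximity_fraction(
    instances: Sequence[MotifInstance],
    exons: Mapping[str, Sequence[tuple[int, int]]],
    within_bp: int = 1000,
) -> float:
    """Fraction of instances within ``within_bp`` (closed, <=) of an exon."""
    if not instances:
        return 0.0
    return float(np.mean(_min_distances(instances, exons) <= within_bp))


def downsampled_proximity_test(
    instances_a: Sequence[MotifInstance],
    exons_a: Mapping[str, Sequence[tuple[int, int]]],
    instances_b: Sequence[MotifInstance],
    exons_b: Mapping[str, Sequence[tuple[int, int]]],
    within_bp: int = 1000,
    n_iter: int = 10,
    seed: int | np.random.Generator = 0,
) -> tuple[float, pd.DataFrame]:
    """Exon-proximity contrast between two genomes with matched annotation bp.

    Genome *a*'s exons are repeatedly downsampled (uniform random order,
    stopping at the first exon that meets/exceeds *b*'s total annotated
    bp), the 2x2 within/beyond-1kb table is tested with Fisher's Exact
    Test, and the maximum p over ``n_iter`` iterations is reported as the
    conservative p-value, alongside the per-iteration table.
    """
    rng = np.random.default_rng(seed)
    flat_a = [(c, s, e) for c, ivs in exons_a.items() for s, e in ivs]
    flat_b = [(c, s, e) for c, ivs in exons_b.items() for s, e in ivs]
    bp_a = sum(e - s for _, s, e in flat_a)
    bp_b = sum(e - s for _, s, e in flat_b)
    if bp_a < bp_b:
        logger.info("annotation of b larger than a; swapping roles")
        return downsampled_proximity_test(
            instances_b, exons_b, instances_a, exons_a, within_bp, n_iter, rng
        )

    dists_b = _min_distances(instances_b, exons_b)
    within_b = int(np.sum(dists_b <= within_bp))
    beyond_b = len(instances_b) - within_b

    rows = []
    for it in range(n_iter):
        order = rng.permutation(len(flat_a))
        picked: dict[str, list[tuple[int, int]]] = {}
        total = 0
        for idx in order:
            c, s, e = flat_a[idx]
            picked.setdefault(c, []).append((s, e))
            total += e - s
            if total >= bp_b:
                break
        dists_a = _min_distances(instances_a, picked)
        within_a = int(np.sum(dists_a <= within_bp))
        beyond_a = len(instances_a) - within_a
        _, p = stats.fisher_exact(
            [[within_a, beyond_a], [within_b, beyond_b]], alternative="two-sided"
        )
        rows.append(
            dict(
                iteration=it,
                downsampled_bp=total,
                within_a=within_a,
                beyond_a=beyond_a,
                within_b=within_b,
                beyond_b=beyond_b,
                p=p,
            )
        )
    table = pd.DataFrame(rows)
    return float(table["p"].max()), table


def write_bed(instances: Sequence[MotifInstance], path: str | Path) -> None:
    """BED6: name = matched motif string, score = 0."""
    with open(path, "w") as fh:
        for inst in instances:
            motif = inst.seq if inst.strand == "+" else revcomp(inst.seq)
            fh.write(
                f"{inst.chrom}\t{inst.start}\t{inst.end}\t{motif}\t0\t{inst.strand}\n"
            )


def read_bed(path: str | Path) -> list[MotifInstance]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            chrom, start, end, name, _score, strand = line.split("\t")[:6]
            strand = strand.strip()
            seq = name if strand == "+" else revcomp(name)
            out.append(MotifInstance(chrom, int(start), int(end), strand, seq))
    return out
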