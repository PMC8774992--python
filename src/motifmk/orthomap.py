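"""Flank-extended motif segments, cross-genome lifting, and per-site records.

A motif instance is extended symmetrically by ``flank_bp`` (7 bp by
default, giving 21-bp segments for the 7-bp core) and lifted to a second
assembly through ungapped alignment blocks with liftOver-like semantics:
a segment maps only if it lies inside a single block whose alignment
identity meets the ``min_match`` threshold (0.95 by default). Source and
destination sequences are compared in whichever orientation (forward or
reverse complement) minimizes the number of differences, and each
segment position is classified core/flank and fixed-difference/
polymorphic; these per-site records are the input of the motif-level
McDonald-Kreitman machinery in :mod:`motifmk.mk`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genome import GenomeSequence, revcomp
from .scan import MotifInstance

logger = logging.getLogger(__name__)

MAPPING_STATUSES = ("mapped", "unmapped", "split", "below_min_match", "filtered_chrom")

#: Chromosome classes excluded from mapping (unreliable alignment).
EXCLUDED_CLASSES = frozenset({"unassembled"})


@dataclass(frozen=True)
class MotifSegment:
    """A motif instance with symmetric flanks; the MK resampling unit."""

    instance: MotifInstance
    seg_start: int
    seg_end: int
    flank_bp: int

    @property
    def chrom(self) -> str:
        return self.instance.chrom

    @property
    def length(self) -> int:
        return self.seg_end - self.seg_start

    @property
    def core_span(self) -> tuple[int, int]:
        """Core offsets within the segment (half-open)."""
        return self.flank_bp, self.flank_bp + (self.instance.end - self.instance.start)

    def site_classes(self) -> list[str]:
        lo, hi = self.core_span
        return ["core" if lo <= i < hi else "flank" for i in range(self.length)]


@dataclass
class BlockMap:
    """Ungapped pairwise alignment blocks with a minMatch threshold."""

    blocks: pd.DataFrame
    min_match: float = 0.95

    def __post_init__(self) -> None:
        b = self.blocks
        src_len = b["src_end"] - b["src_start"]
        dst_len = b["dst_end"] - b["dst_start"]
        if (src_len != dst_len).any():
            raise ValueError("malformed block: src/dst length mismatch")
        if ((b["identity"] < 0) | (b["identity"] > 1)).any():
            raise ValueError("block identity outside [0, 1]")
        if not b["dst_strand"].isin(["+", "-"]).all():
            raise ValueError("block dst_strand must be + or -")
        self.blocks = b.sort_values(["src_chrom", "src_start"], ignore_index=True)
        for _, grp in self.blocks.groupby("src_chrom"):
            if (grp["src_start"].values[1:] < grp["src_end"].values[:-1]).any():
                raise ValueError("blocks overlap on the source genome")

    @classmethod
    def identity(cls, lengths: Mapping[str, int], min_match: float = 0.95) -> "BlockMap":
        rows = [
            dict(src_chrom=c, src_start=0, src_end=l, dst_chrom=c,
                 dst_start=0, dst_end=l, dst_strand="+", identity=1.0)
            for c, l in lengths.items()
        ]
        return cls(pd.DataFrame(rows), min_match)


@dataclass
class MappedSegmentPair:
    """A segment with its lift outcome and (when mapped) both sequences."""

    segment: MotifSegment
    status: str
    dst_chrom: str | None = None
    dst_start: int | None = None
    dst_end: int | None = None
    dst_strand: str | None = None
    src_seq: str | None = None
    dst_seq: str | None = None

    def __post_init__(self) -> None:
        if self.status not in MAPPING_STATUSES:
            raise ValueError(f"unknown mapping status {self.status!r}")
        if self.status == "mapped" and (
            self.src_seq is None or self.dst_seq is None
            or len(self.src_seq) != len(self.dst_seq)
        ):
            raise ValueError("mapped pair requires equal-length sequences")


def build_segments(
    instances: Sequence[MotifInstance],
    genome: GenomeSequence,
    flank_bp: int = 7,
) -> list[MotifSegment]:
    """Extend instances by ``flank_bp`` on each side; drop edge overruns.

    Segments that would overrun a chromosome end are dropped rather than
    trimmed, so every retained segment has identical length and per-class
    site totals stay proportional to segment counts.
    """
    if flank_bp < 0:
        raise ValueError("flank_bp must be >= 0")
    lengths = genome.lengths()
    out, dropped = [], 0
    for inst in instances:
        s, e = inst.start - flank_bp, inst.end + flank_bp
        if s < 0 or e > lengths[inst.chrom]:
            dropped += 1
            continue
        out.append(MotifSegment(inst, s, e, flank_bp))
    if dropped:
        logger.info("build_segments: dropped %d edge-overrunning segments", dropped)
    return out


def filter_segments(
    segments: Sequence[MotifSegment],
    chrom_classes: Mapping[str, str],
) -> tuple[list[MotifSegment], dict[str, int]]:
    """Drop segments on unassembled/heterochromatic chromosomes."""
    kept, rejected = [], {}
    for seg in segments:
        cls = chrom_classes.get(seg.chrom, "autosome")
        if cls in EXCLUDED_CLASSES:
            rejected[cls] = rejected.get(cls, 0) + 1
        else:
            kept.append(seg)
    if rejected:
        logger.info("filter_segments: rejected %s", rejected)
    return kept, rejected


def lift_segment(
    segment: MotifSegment,
    block_map: BlockMap,
    src_genome: GenomeSequence | None = None,
    dst_genome: GenomeSequence | None = None,
) -> MappedSegmentPair:
    """Lift one segment through the block map (liftOver-like semantics).

    mapped: inside a single block with identity >= min_match; split:
    touching two or more blocks or hanging off a block edge;
    below_min_match: inside one block of insufficient identity; unmapped:
    no block. When genomes are given, mapped pairs carry both sequences
    (destination bases reverse-complemented for '-' blocks).
    """
    b = block_map.blocks
    hits = b[
        (b["src_chrom"] == segment.chrom)
        & (b["src_start"] < segment.seg_end)
        & (b["src_end"] > segment.seg_start)
    ]
    if len(hits) == 0:
        return MappedSegmentPair(segment, "unmapped")
    within = hits[
        (hits["src_start"] <= segment.seg_start) & (hits["src_end"] >= segment.seg_end)
    ]
    if len(within) == 0:
        return MappedSegmentPair(segment, "split")
    block = within.iloc[0]
    if block["identity"] < block_map.min_match:
        return MappedSegmentPair(segment, "below_min_match")
    o1 = segment.seg_start - int(block["src_start"])
    o2 = segment.seg_end - int(block["src_start"])
    if block["dst_strand"] == "+":
        d1, d2 = int(block["dst_start"]) + o1, int(block["dst_start"]) + o2
    else:
        d1, d2 = int(block["dst_end"]) - o2, int(block["dst_end"]) - o1
    src_seq = dst_seq = None
    if src_genome is not None and dst_genome is not None:
        src_seq = src_genome.chroms[segment.chrom][segment.seg_start:segment.seg_end]
        dst_raw = dst_genome.chroms[str(block["dst_chrom"])][d1:d2]
        dst_seq = dst_raw if block["dst_strand"] == "+" else revcomp(dst_raw)
    return MappedSegmentPair(
        segment, "mapped",
        dst_chrom=str(block["dst_chrom"]), dst_start=d1, dst_end=d2,
        dst_strand=str(block["dst_strand"]), src_seq=src_seq, dst_seq=dst_seq,
    )


def count_differences(seq_a: str, seq_b: str) -> tuple[int, str]:
    """Minimum of forward and reverse-complement Hamming distances.

    Returns (n_diff, orientation); ties break toward 'forward'.
    """
    if len(seq_a) != len(seq_b):
        raise ValueError("sequences must have equal length")
    fwd = sum(x != y for x, y in zip(seq_a, seq_b))
    rev = sum(x != y for x, y in zip(seq_a, revcomp(seq_b)))
    return (fwd, "forward") if fwd <= rev else (rev, "reverse")


def map_segments(
    segments: Sequence[MotifSegment],
    block_map: BlockMap,
    src_genome: GenomeSequence,
    dst_genome: GenomeSequence,
    chrom_classes: Mapping[str, str] | None = None,
) -> list[MappedSegmentPair]:
    """Filter + lift a segment collection; statuses partition the input."""
    if chrom_classes is None:
        chrom_classes = src_genome.classes
    pairs: list[MappedSegmentPair] = []
    for seg in segments:
        if chrom_classes.get(seg.chrom, "autosome") in EXCLUDED_CLASSES:
            pairs.append(MappedSegmentPair(seg, "filtered_chrom"))
        else:
            pairs.append(lift_segment(seg, block_map, src_genome, dst_genome))
    counts = pd.Series([p.status for p in pairs]).value_counts().to_dict()
    logger.info("map_segments: %s", counts)
    return pairs


def snp_positions(
    variants: pd.DataFrame, maf_min: float = 0.05, snp_only: bool = True
) -> dict[str, set[int]]:
    """Per-chromosome 0-based positions of variants surviving the filters.

    Keeps variants with minor allele frequency strictly greater than
    ``maf_min`` (5% by default) and, with ``snp_only``, only single-
    nucleotide variants (indels omitted).
    """
    if variants.empty:
        return {}
    df = variants.copy()
    maf = np.minimum(df["af"], 1.0 - df["af"])
    df = df[maf > maf_min]
    if snp_only:
        df = df[df["is_snp"]]
    return {c: set(g["pos"].astype(int)) for c, g in df.groupby("chrom")}


def classify_segment_sites(
    pair: MappedSegmentPair,
    snp_sites: Mapping[str, set[int]],
    segment_id: int = 0,
) -> pd.DataFrame:
    """Per-site core/flank, fixed-difference and polymorphism calls.

    Fixed differences are read off the orientation chosen by
    :func:`count_differences`; a site that is both polymorphic and
    divergent is counted as polymorphic only, avoiding double counting.
    """
    if pair.status != "mapped":
        raise ValueError(f"can only classify mapped pairs (status={pair.status})")
    n_diff, orientation = count_differences(pair.src_seq, pair.dst_seq)
    dst = pair.dst_seq if orientation == "forward" else revcomp(pair.dst_seq)
    seg = pair.segment
    positions = np.arange(seg.seg_start, seg.seg_end)
    chrom_snps = snp_sites.get(seg.chrom, set())
    poly = np.array([int(p) in chrom_snps for p in positions])
    fixed = np.array([a != b for a, b in zip(pair.src_seq, dst)])
    fixed = fixed & ~poly  # polymorphic wins
    return pd.DataFrame(
        dict(
            segment=segment_id,
            chrom=seg.chrom,
            pos=positions,
            site_class=seg.site_classes(),
            fixed_diff=fixed.astype(int),
            polymorphic=poly.astype(int),
        )
    )


def classify_pairs(
    pairs: Sequence[MappedSegmentPair],
    variants: pd.DataFrame,
    maf_min: float = 0.05,
    snp_only: bool = True,
) -> pd.DataFrame:
    """Site records for every mapped pair, after the MAF>5%/SNP-only filter."""
    sites = snp_positions(variants, maf_min=maf_min, snp_only=snp_only)
    frames = [
        classify_segment_sites(p, sites, segment_id=i)
        for i, p in enumerate(pairs)
        if p.status == "mapped"
    ]
    if not frames:
        return pd.DataFrame(
            columns=["segment", "chrom", "pos", "site_class", "fixed_diff", "polymorphic"]
        )
    return pd.concat(frames, ignore_index=True)
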