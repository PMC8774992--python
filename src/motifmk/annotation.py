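"""Gene models (TSS, strand, exons) and GFF3 round-trips."""

from __future__ import annotations


from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import gffutils

GFF3_HEADER = "##gff-version 3"


@dataclass(frozen=True)
class GeneModel:
    """A gene with its exons; coordinates 0-based half-open.

    The TSS is the 5' end of the gene respecting strand: ``start`` for
    '+' genes, ``end - 1`` for '-' genes (the coordinate of the first
    transcribed base).
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        if not 0 <= self.start < self.end:
            raise ValueError(f"bad gene interval [{self.start}, {self.end})")
        if not self.exons:
            raise ValueError(f"gene {self.gene_id} has no exons")

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1


def write_gff3(genes: Iterable[GeneModel], path: str | Path) -> None:
    """Write gene models as GFF3 (1-based inclusive on disk)."""
    lines = [GFF3_HEADER]
    for g in genes:
        lines.append(
            f"{g.chrom}\tmotifmk\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t"
            f"ID={g.gene_id}"
        )
        for i, (es, ee) in enumerate(g.exons, start=1):
            lines.append(
                f"{g.chrom}\tmotifmk\texon\t{es + 1}\t{ee}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id}.e{i};Parent={g.gene_id}"
            )
    Path(path).write_text("\n".join(lines) + "\n")


def read_gff3(path: str | Path) -> list[GeneModel]:
    """Read gene models from GFF3 back into 0-based half-open coordinates."""
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    genes = []
    for gene in db.features_of_type("gene"):
        exons = tuple(
            sorted(
                (e.start - 1, e.end)
                for e in db.children(gene, featuretype="exon")
            )
        )
        genes.append(
            GeneModel(
                gene_id=gene.id,
                chrom=gene.seqid,
                start=gene.start - 1,
                end=gene.end,
                strand=gene.strand,
                exons=exons,
            )
        )
    genes.sort(key=lambda g: (g.chrom, g.start, g.gene_id))
    return genes


def exon_intervals(genes: Sequence[GeneModel]) -> dict[str, list[tuple[int, int]]]:
    """Per-chromosome sorted exon (start, end) intervals."""
    out: dict[str, list[tuple[int, int]]] = {}
    for g in genes:
        out.setdefault(g.chrom, []).extend(g.exons)
    for chrom in out:
        out[chrom].sort()
    return out
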