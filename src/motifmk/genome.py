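"""Genome sequence container, chromosome classes, and FASTA round-trips.

Coordinates are 0-based half-open (BED convention) everywhere in this
package. Chromosome *classes* follow the Drosophila convention used in
the analyses: the X, the major autosomal arms, the small "dot" (4th)
chromosome, and unassembled/heterochromatic scaffolds (chrU, *Het),
which are excluded from ortholog mapping because alignment there is
unreliable.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

CHROM_CLASSES = ("X", "autosome", "dot", "unassembled")

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-preserving)."""
    return seq.translate(_COMPLEMENT)[::-1]


def classify_chrom(name: str) -> str:
    """Heuristic chromosome class from a UCSC-style chromosome name.

    ``chrX`` -> X; ``chr4`` -> dot; ``chrU*``, ``*Het``, ``*random`` ->
    unassembled; everything else -> autosome.
    """
    base = name.removeprefix("chr")
    if base.upper().startswith("U") or name.endswith(("Het", "random")):
        return "unassembled"
    if re.fullmatch(r"X[LR]?", base, flags=re.IGNORECASE):
        return "X"
    if base == "4":
        return "dot"
    return "autosome"


@dataclass
class GenomeSequence:
    """Named chromosomes (uppercase DNA over A/C/G/T/N) with class labels."""

    chroms: dict[str, str]
    classes: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.chroms)) != len(self.chroms):
            raise ValueError("duplicate chromosome names")
        for name, seq in self.chroms.items():
            if not seq:
                raise ValueError(f"zero-length chromosome {name!r}")
        for name in self.chroms:
            cls = self.classes.get(name)
            if cls is None:
                self.classes[name] = classify_chrom(name)
            elif cls not in CHROM_CLASSES:
                raise ValueError(f"unknown chromosome class {cls!r} for {name!r}")

    def __len__(self) -> int:
        return sum(len(s) for s in self.chroms.values())

    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.chroms.items()}

    @classmethod
    def from_fasta(
        cls, path: str | Path, classes: Mapping[str, str] | None = None
    ) -> "GenomeSequence":
        chroms = {
            rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")
        }
        return cls(chroms, dict(classes) if classes else {})

    def to_fasta(self, path: str | Path) -> None:
        records = [
            SeqRecord(Seq(seq), id=name, description="")
            for name, seq in self.chroms.items()
        ]
        SeqIO.write(records, str(path), "fasta")


def total_bp(intervals: Iterable[tuple[int, int]]) -> int:
    """Total bp covered by (start, end) half-open intervals (no merging)."""
    return sum(end - start for start, end in intervals)
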