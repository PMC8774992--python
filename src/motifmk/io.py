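"""File-format round-trips: VCF (pysam), BlockMap TSV, narrowPeak, read BED."""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import pandas as pd
import pysam

VARIANT_COLUMNS = ["chrom", "pos", "ref", "alt", "af", "is_snp"]

NARROWPEAK_COLUMNS = [
    "chrom", "start", "end", "name", "score", "strand",
    "signalValue", "pValue", "qValue", "peak",
]

BLOCK_COLUMNS = [
    "src_chrom", "src_start", "src_end",
    "dst_chrom", "dst_start", "dst_end", "dst_strand", "identity",
]


def write_vcf(
    variants: pd.DataFrame, path: str | Path, contigs: Mapping[str, int]
) -> None:
    """Write a variant table (0-based ``pos``) as uncompressed VCF v4.2."""
    header = pysam.VariantHeader()
    for name, length in contigs.items():
        header.contigs.add(name, length=length)
    header.info.add("AF", "A", "Float", "Allele frequency")
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for row in variants.sort_values(["chrom", "pos"]).itertuples():
            rec = vcf.new_record(
                contig=row.chrom,
                start=int(row.pos),
                alleles=(row.ref, row.alt),
            )
            rec.info["AF"] = float(row.af)
            vcf.write(rec)


def read_vcf(path: str | Path) -> pd.DataFrame:
    """Read a VCF into the variant-table schema (0-based ``pos``).

    AF is taken from INFO when present, otherwise computed from the
    genotype calls.
    """
    rows = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            for i, alt in enumerate(rec.alts or ()):
                if "AF" in rec.info:
                    af = rec.info["AF"]
                    af = float(af[i] if isinstance(af, tuple) else af)
                else:
                    calls = [
                        a
                        for s in rec.samples.values()
                        for a in s["GT"]
                        if a is not None
                    ]
                    af = calls.count(i + 1) / len(calls) if calls else float("nan")
                rows.append(
                    dict(
                        chrom=rec.chrom,
                        pos=rec.start,
                        ref=rec.ref,
                        alt=alt,
                        af=af,
                        is_snp=len(rec.ref) == 1 and len(alt) == 1,
                    )
                )
    return pd.DataFrame(rows, columns=VARIANT_COLUMNS)


def write_blocks(blocks: pd.DataFrame, path: str | Path) -> None:
    blocks.to_csv(path, sep="\t", index=False, columns=BLOCK_COLUMNS)


def read_blocks(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"src_chrom": str, "dst_chrom": str})


def write_narrowpeak(peaks: pd.DataFrame, path: str | Path) -> None:
    peaks.to_csv(path, sep="\t", index=False, header=False,
                 columns=NARROWPEAK_COLUMNS)


def read_narrowpeak(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", names=NARROWPEAK_COLUMNS,
                       dtype={"chrom": str})


def write_read_bed(reads: pd.DataFrame, path: str | Path) -> None:
    """Read positions as BED6 single-base intervals."""
    df = reads.assign(
        end=reads["pos"] + 1, name="read", score=0, strand="."
    )
    df.to_csv(path, sep="\t", index=False, header=False,
              columns=["chrom", "pos", "end", "name", "score", "strand"])


def read_read_bed(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", usecols=[0, 1],
                     names=["chrom", "pos"], dtype={0: str})
    return df
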