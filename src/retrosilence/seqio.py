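"""Readers and writers for the plain-text genomics formats the pipeline touches.

FASTA/FASTQ parsing goes through pysam's fastx reader; SAM and VCF also go
through pysam; BED/GFF3/TSV are handled with pandas plus small format shims
(the GFF3 subset read here is the gene/exon layout this package itself
writes).
"""

from __future__ import annotations

import hashlib
import os
from dataclasses import dataclass
from typing import Iterable, Iterator

import pandas as pd
import pysam

BED_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


@dataclass
class FastqRead:
    """One sequencing read (4-line FASTQ record, Phred+33 qualities)."""

    name: str
    seq: str
    qual: str

    def __len__(self) -> int:
        return len(self.seq)


# ---------------------------------------------------------------------------
# FASTA / FASTQ


def write_fasta(path: str | os.PathLike, seqs: dict[str, str], width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    seqs: dict[str, str] = {}
    with pysam.FastxFile(str(path)) as fh:
        for entry in fh:
            seqs[entry.name] = entry.sequence.upper()
    return seqs


def write_fastq(path: str | os.PathLike, reads: Iterable[FastqRead]) -> int:
    n = 0
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.name}\n{r.seq}\n+\n{r.qual}\n")
            n += 1
    return n


def read_fastq(path: str | os.PathLike) -> Iterator[FastqRead]:
    with pysam.FastxFile(str(path)) as fh:
        for entry in fh:
            yield FastqRead(entry.name, entry.sequence, entry.quality or "")


# ---------------------------------------------------------------------------
# BED / GFF3


def write_bed(path: str | os.PathLike, df: pd.DataFrame) -> None:
    df.to_csv(path, sep="\t", header=False, index=False, columns=BED_COLUMNS)


def read_bed(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, names=BED_COLUMNS, comment="#")
    return df


def write_gff3(path: str | os.PathLike, genes: pd.DataFrame, exons: pd.DataFrame) -> None:
    """Write genes and their exons as a minimal GFF3 (1-based inclusive on disk)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes.itertuples():
            fh.write(
                f"{g.chrom}\tretrosilence\tgene\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\tID={g.gene_id}\n"
            )
            for e in exons[exons["gene_id"] == g.gene_id].itertuples():
                fh.write(
                    f"{g.chrom}\tretrosilence\texon\t{e.start + 1}\t{e.end}\t.\t"
                    f"{g.strand}\t.\tParent={g.gene_id}\n"
                )


def read_gff3(path: str | os.PathLike) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Parse the gene/exon GFF3 layout back into 0-based half-open frames."""
    genes, exons = [], []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            chrom, _src, ftype, start, end, _score, strand, _phase, attrs = (
                line.rstrip("\n").split("\t")
            )
            attr = dict(kv.split("=", 1) for kv in attrs.split(";") if "=" in kv)
            if ftype == "gene":
                genes.append(
                    {
                        "gene_id": attr["ID"],
                        "chrom": chrom,
                        "start": int(start) - 1,
                        "end": int(end),
                        "strand": strand,
                    }
                )
            elif ftype == "exon":
                exons.append(
                    {"gene_id": attr["Parent"], "start": int(start) - 1, "end": int(end)}
                )
    return pd.DataFrame(genes), pd.DataFrame(exons)


# ---------------------------------------------------------------------------
# VCF


def write_vcf(
    path: str | os.PathLike, snps: pd.DataFrame, contigs: dict[str, int]
) -> None:
    """Write biallelic strain SNPs (columns chrom, pos [0-based], ref, alt)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for name, length in contigs.items():
            fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for s in snps.itertuples():
            fh.write(f"{s.chrom}\t{s.pos + 1}\tsnp{s.Index}\t{s.ref}\t{s.alt}\t.\tPASS\t.\n")


def read_vcf(path: str | os.PathLike) -> pd.DataFrame:
    rows = []
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            rows.append(
                {
                    "chrom": rec.chrom,
                    "pos": rec.pos - 1,
                    "ref": rec.ref,
                    "alt": rec.alts[0] if rec.alts else ".",
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# misc


def write_tsv(path: str | os.PathLike, df: pd.DataFrame, header_comment: str | None = None) -> None:
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_tsv(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def sha256_file(path: str | os.PathLike) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()
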