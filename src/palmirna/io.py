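"""Readers/writers for the plain-text formats the pipeline exchanges.

FASTA/FASTQ go through Biopython; BED6, GFF3 and TSV tables are simple
tab-separated text written deterministically (stable row order, no
timestamps) so that identical runs are byte-identical.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path: str | Path, records: dict[str, str]) -> None:
    recs = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in records.items()
    ]
    SeqIO.write(recs, str(path), "fasta")


def read_fastq(path: str | Path) -> Iterator[tuple[str, str, list[int]]]:
    """Yield (read id, sequence, per-base Phred qualities)."""
    for rec in SeqIO.parse(str(path), "fastq"):
        yield rec.id, str(rec.seq).upper(), rec.letter_annotations["phred_quality"]


def write_fastq(path: str | Path, reads: Iterable[tuple[str, str, str]]) -> None:
    """Write (id, sequence, quality string) triples as Phred+33 FASTQ."""
    with open(path, "w") as fh:
        for rid, seq, qual in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")


def write_bed6(
    path: str | Path,
    rows: Iterable[tuple[str, int, int, str, int | float, str]],
) -> None:
    with open(path, "w") as fh:
        for chrom, start, end, name, score, strand in rows:
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\t{score}\t{strand}\n")


def read_bed6(path: str | Path) -> list[tuple[str, int, int, str, float, str]]:
    out = []
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        chrom, start, end, name, score, strand = line.split("\t")[:6]
        out.append((chrom, int(start), int(end), name, float(score), strand))
    return out


def write_gff3(path: str | Path, rows: Iterable[tuple]) -> None:
    """Rows: (seqid, source, type, start1, end1, score, strand, attributes)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for seqid, source, ftype, start, end, score, strand, attrs in rows:
            fh.write(
                f"{seqid}\t{source}\t{ftype}\t{start}\t{end}\t{score}\t{strand}\t.\t{attrs}\n"
            )
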