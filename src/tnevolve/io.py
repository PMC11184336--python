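"""FASTA/FASTQ helpers.

Reading goes through Biopython's SeqIO.  Bulk FASTQ writing is done with
plain string formatting because simulated runs emit hundreds of thousands of
multi-kilobase reads; the format is fixed four-line records with a constant
placeholder quality.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO

Record = tuple[str, str]


def read_fasta(path: str | Path) -> list[Record]:
    return [(r.id, str(r.seq).upper()) for r in SeqIO.parse(str(path), "fasta")]


def read_fastq(path: str | Path) -> Iterator[Record]:
    for r in SeqIO.parse(str(path), "fastq"):
        yield r.id, str(r.seq).upper()


def read_reads(path: str | Path) -> Iterator[Record]:
    """Read sequences from FASTA or FASTQ, sniffing the format."""
    path = Path(path)
    with open(path) as fh:
        first = fh.read(1)
    if first == "@":
        yield from read_fastq(path)
    else:
        yield from read_fasta(path)


def write_fasta(records: Iterable[Record], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_fastq(records: Iterable[Record], path: str | Path, quality_char: str = "I") -> None:
    """Write four-line FASTQ records with a uniform placeholder quality.

    An empty iterable yields a valid, empty file.
    """
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f"@{name}\n{seq}\n+\n{quality_char * len(seq)}\n")
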