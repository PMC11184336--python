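"""Small sequence helpers shared across modules."""

from __future__ import annotations

from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq

# Sense codons of the standard code, grouped by encoded amino acid.
CODON_TABLE: dict[str, str] = dict(standard_dna_table.forward_table)
STOP_CODONS: tuple[str, ...] = tuple(standard_dna_table.stop_codons)
AA_TO_CODONS: dict[str, tuple[str, ...]] = {}
for _codon, _aa in sorted(CODON_TABLE.items()):
    AA_TO_CODONS.setdefault(_aa, ())
    AA_TO_CODONS[_aa] = AA_TO_CODONS[_aa] + (_codon,)

AMINO_ACIDS: str = "".join(sorted(AA_TO_CODONS))

DNA_ALPHABET = frozenset("ACGTN")


def translate(cds: str) -> str:
    """Translate a DNA coding sequence (standard table, stops as ``*``)."""
    return str(Seq(cds).translate())


def revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def is_dna(seq: str) -> bool:
    return set(seq.upper()) <= DNA_ALPHABET
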