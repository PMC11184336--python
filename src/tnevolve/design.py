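"""The designed-mutation catalogue of a shuffled variant library.

A combinatorial mutant library is built from a fixed catalogue of designed
codon substitutions in a reference CDS; every library member carries a subset
of them.  The catalogue is the unit of genotyping and enrichment scoring, so
it is validated strictly: each designed wild-type codon must match the
reference, each substitution must change the amino acid, and mutation ids
must be unique.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from tnevolve._seq import CODON_TABLE, translate

DESIGN_COLUMNS = ["mutation_id", "aa_pos_1based", "wt_aa", "mut_aa", "wt_codon", "mut_codon"]


class DesignIntegrityError(ValueError):
    """A design table is internally inconsistent or contradicts the reference."""


@dataclass(frozen=True)
class DesignedMutation:
    """One designed codon substitution.

    Attributes
    ----------
    mutation_id : str
        Unique identifier; by convention the ``<wt><pos><mut>`` label
        (e.g. ``V356L``).
    aa_pos : int
        1-based codon position in the reference protein.
    wt_aa, mut_aa : str
        Reference and substituted amino acids (single letter); must differ.
    wt_codon, mut_codon : str
        The reference codon and the designed replacement codon.
    """

    mutation_id: str
    aa_pos: int
    wt_aa: str
    mut_aa: str
    wt_codon: str
    mut_codon: str

    def __post_init__(self) -> None:
        if self.aa_pos < 1:
            raise DesignIntegrityError(f"{self.mutation_id}: aa_pos must be >= 1")
        for codon, aa, name in (
            (self.wt_codon, self.wt_aa, "wt"),
            (self.mut_codon, self.mut_aa, "mut"),
        ):
            if CODON_TABLE.get(codon) != aa:
                raise DesignIntegrityError(
                    f"{self.mutation_id}: {name}_codon {codon} does not encode {aa}"
                )
        if self.wt_aa == self.mut_aa:
            raise DesignIntegrityError(f"{self.mutation_id}: synonymous substitution")

    @property
    def label(self) -> str:
        return f"{self.wt_aa}{self.aa_pos}{self.mut_aa}"


@dataclass
class MutationLibraryDesign:
    """Reference CDS plus the catalogue of designed codon substitutions."""

    reference_cds: str
    mutations: list[DesignedMutation] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.reference_cds = self.reference_cds.upper()
        if len(self.reference_cds) % 3 != 0:
            raise DesignIntegrityError("reference CDS length is not a multiple of 3")
        protein = translate(self.reference_cds)
        seen: set[str] = set()
        positions: set[int] = set()
        for m in self.mutations:
            if m.mutation_id in seen:
                raise DesignIntegrityError(f"duplicate mutation_id {m.mutation_id}")
            seen.add(m.mutation_id)
            if m.aa_pos in positions:
                raise DesignIntegrityError(
                    f"{m.mutation_id}: second designed mutation at codon {m.aa_pos}"
                )
            positions.add(m.aa_pos)
            ref_codon = self.codon_at(m.aa_pos)
            if ref_codon != m.wt_codon:
                raise DesignIntegrityError(
                    f"{m.mutation_id}: wt_codon {m.wt_codon} != reference codon "
                    f"{ref_codon} at position {m.aa_pos}"
                )
            if m.aa_pos > len(protein):
                raise DesignIntegrityError(f"{m.mutation_id}: position beyond protein")

    def __len__(self) -> int:
        return len(self.mutations)

    @property
    def n_codons(self) -> int:
        """Codon count of the reference, excluding the stop."""
        n = len(self.reference_cds) // 3
        return n - 1 if translate(self.reference_cds).endswith("*") else n

    @property
    def ids(self) -> list[str]:
        return [m.mutation_id for m in self.mutations]

    def codon_at(self, aa_pos: int) -> str:
        i = 3 * (aa_pos - 1)
        return self.reference_cds[i : i + 3]

    def by_id(self, mutation_id: str) -> DesignedMutation:
        for m in self.mutations:
            if m.mutation_id == mutation_id:
                return m
        raise KeyError(mutation_id)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (m.mutation_id, m.aa_pos, m.wt_aa, m.mut_aa, m.wt_codon, m.mut_codon)
                for m in self.mutations
            ],
            columns=DESIGN_COLUMNS,
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def load_design(tsv: str | Path, reference_cds: str) -> MutationLibraryDesign:
    """Load and validate a design table against the reference CDS.

    Raises
    ------
    DesignIntegrityError
        Naming the offending row when a wild-type codon does not match the
        reference, a mutation id is duplicated, or a substitution is
        synonymous.
    """
    df = pd.read_csv(tsv, sep="\t", dtype={"mutation_id": str})
    missing = set(DESIGN_COLUMNS) - set(df.columns)
    if missing:
        raise DesignIntegrityError(f"design table missing columns: {sorted(missing)}")
    mutations = [
        DesignedMutation(
            mutation_id=row.mutation_id,
            aa_pos=int(row.aa_pos_1based),
            wt_aa=row.wt_aa,
            mut_aa=row.mut_aa,
            wt_codon=row.wt_codon,
            mut_codon=row.mut_codon,
        )
        for row in df.itertuples()
    ]
    return MutationLibraryDesign(reference_cds=reference_cds, mutations=mutations)
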