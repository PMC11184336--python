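"""Candidate hyperactive substitutions from a protein alignment.

A candidate is an alignment column where the homolog consensus is strongly
conserved but the target sequence carries a different residue — the idea
being that a residue most family members kept is likely beneficial, so
swapping it into the target may raise activity.  The consensus is computed
*excluding* the target row, frequencies over non-gap, non-ambiguous
residues only.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import AlignIO

from tnevolve._seq import AMINO_ACIDS
from tnevolve.io import Record

_GAPS = {"-", "."}
_AMBIGUOUS = {"X", "B", "Z", "*"}


class RaggedAlignmentError(ValueError):
    """Alignment rows have unequal lengths."""


@dataclass
class AlignmentProfile:
    """Per-column residue frequencies of a protein alignment.

    ``frequencies`` is a (n_columns x 20) DataFrame over the amino-acid
    alphabet, each row summing to 1 over non-gap, non-ambiguous residues
    (all-gap columns sum to 0 and are flagged in ``all_gap``).
    ``coverage`` is the per-column fraction of rows with an unambiguous
    residue.
    """

    frequencies: pd.DataFrame
    coverage: np.ndarray
    all_gap: np.ndarray
    n_sequences: int

    @property
    def n_columns(self) -> int:
        return len(self.frequencies)

    def consensus(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-column (consensus residue, consensus frequency); all-gap
        columns yield ('-', 0)."""
        freq = self.frequencies.to_numpy()
        idx = freq.argmax(axis=1)
        res = np.array(list(self.frequencies.columns))[idx]
        top = freq[np.arange(len(idx)), idx]
        res[self.all_gap] = "-"
        return res, top


@dataclass(frozen=True)
class CandidateSubstitution:
    """A conserved consensus residue absent from the target sequence.

    ``position`` is 1-based in target-sequence numbering (target gaps
    excluded); ``frequency`` is the consensus frequency among non-target
    rows at that column.
    """

    position: int
    target_aa: str
    consensus_aa: str
    frequency: float
    coverage: float

    def __post_init__(self) -> None:
        if self.target_aa == self.consensus_aa:
            raise ValueError("candidate must change the residue")
        if not 0.0 < self.frequency <= 1.0:
            raise ValueError("frequency must be in (0, 1]")

    @property
    def label(self) -> str:
        return f"{self.target_aa}{self.position}{self.consensus_aa}"


def _as_records(msa) -> list[Record]:
    if isinstance(msa, (str, Path)):
        aln = AlignIO.read(str(msa), "fasta")
        return [(r.id, str(r.seq).upper()) for r in aln]
    return [(name, seq.upper()) for name, seq in msa]


def _matrix(records: list[Record]) -> np.ndarray:
    lengths = {len(s) for _, s in records}
    if len(lengths) > 1:
        raise RaggedAlignmentError(f"rows have unequal lengths: {sorted(lengths)}")
    return np.array([list(s) for _, s in records])


def column_frequencies(msa) -> AlignmentProfile:
    """Gap-aware per-column residue frequencies.

    ``msa`` is an aligned-FASTA path or an iterable of ``(id, sequence)``
    pairs.  Gaps and ambiguous residues (X, B, Z) are excluded from the
    denominators.
    """
    records = _as_records(msa)
    mat = _matrix(records)
    aas = list(AMINO_ACIDS)
    counts = np.stack([(mat == aa).sum(axis=0) for aa in aas], axis=1).astype(float)
    denom = counts.sum(axis=1)
    all_gap = denom == 0
    freq = np.divide(counts, denom[:, None], out=np.zeros_like(counts), where=denom[:, None] > 0)
    coverage = denom / len(records)
    return AlignmentProfile(
        frequencies=pd.DataFrame(freq, columns=aas),
        coverage=coverage,
        all_gap=all_gap,
        n_sequences=len(records),
    )


def candidate_substitutions(
    msa,
    target_id: str,
    min_conservation: float = 0.6,
    min_coverage: float = 0.5,
) -> list[CandidateSubstitution]:
    """Find consensus residues the target lacks.

    A column yields a candidate when, among the non-target rows, the modal
    unambiguous residue reaches frequency >= ``min_conservation`` with
    non-gap coverage >= ``min_coverage``, and the target carries a
    different (non-gap) residue there.  Positions are reported in 1-based
    target-sequence numbering and sorted ascending.
    """
    if not 0.5 < min_conservation <= 1.0:
        raise ValueError("min_conservation must be in (0.5, 1]")
    records = _as_records(msa)
    ids = [name for name, _ in records]
    if target_id not in ids:
        raise KeyError(f"target_id {target_id!r} not present in alignment")
    target_seq = dict(records)[target_id]
    others = [(n, s) for n, s in records if n != target_id]
    if not others:
        raise ValueError("alignment has no non-target rows")
    profile = column_frequencies(others)
    cons_res, cons_freq = profile.consensus()

    out: list[CandidateSubstitution] = []
    target_pos = 0
    for col, t_res in enumerate(target_seq):
        if t_res in _GAPS:
            continue
        target_pos += 1
        if t_res in _AMBIGUOUS or profile.all_gap[col]:
            continue
        if (
            cons_freq[col] >= min_conservation
            and profile.coverage[col] >= min_coverage
            and t_res != cons_res[col]
        ):
            out.append(
                CandidateSubstitution(
                    position=target_pos,
                    target_aa=t_res,
                    consensus_aa=str(cons_res[col]),
                    frequency=float(cons_freq[col]),
                    coverage=float(profile.coverage[col]),
                )
            )
    return out


def candidates_to_frame(candidates: list[CandidateSubstitution]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (c.position, c.target_aa, c.consensus_aa, c.frequency, c.coverage, c.label)
            for c in candidates
        ],
        columns=["position", "wt", "consensus", "frequency", "coverage", "label"],
    )
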