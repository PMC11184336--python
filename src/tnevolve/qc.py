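"""Long-read genotyping against a designed-mutation catalogue.

Reads are filtered to full-length CDS alignments, then each designed codon
position is scanned and classified:

* ``WT``  — the read carries the reference codon;
* ``MUT`` — the read carries the designed replacement codon, exactly;
* ``OTHER`` — anything else (sequencing error, indel-disrupted codon, or a
  position outside the aligned span).

Codon matching is exact: a codon that matches neither the wild-type nor the
designed replacement is OTHER and counts toward neither tally, so sequencing
errors cannot inflate either the mutant or wild-type counts.  A variant's
genotype is the set of MUT ids.
"""

from __future__ import annotations

import math
import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable

import edlib
import numpy as np
import pandas as pd

from tnevolve._seq import is_dna, revcomp
from tnevolve.design import MutationLibraryDesign

_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")


@dataclass
class ReadAlignment:
    """A read aligned semi-globally to the reference CDS.

    ``ref_to_read[i]`` is the read position aligned to reference base ``i``
    (-1 where the reference base is deleted or outside the aligned span);
    ``ins_after[i]`` marks a read insertion between reference bases ``i``
    and ``i + 1``.  ``read`` is already in reference orientation.
    """

    read_id: str
    read: str
    strand: str
    ref_start: int
    ref_end: int
    identity: float
    coverage: float
    ref_to_read: np.ndarray
    ins_after: np.ndarray

    def codon(self, aa_pos: int) -> str | None:
        """The read codon at 1-based codon position, or None if the codon is
        not cleanly aligned (indel inside, or not fully covered).

        Unit-cost edit alignments sometimes represent a codon substitution
        as a cancelling insertion/deletion pair instead of mismatches; when
        the flanking anchors sit on the same alignment diagonal the codon is
        rescued by reading the read bases straight off that diagonal, which
        is what an aligner preferring substitutions over indels would
        report.  A genuine (non-cancelling) indel shifts the diagonal and
        still yields None.
        """
        i0 = 3 * (aa_pos - 1)
        m = self.ref_to_read[i0 : i0 + 3]
        if len(m) < 3:
            return None
        c = self._diagonal_codon(i0)
        if c is not None:
            return c
        # fallback for codons whose flanks lack anchors (aligned-span edges)
        if (
            (m >= 0).all()
            and m[1] == m[0] + 1
            and m[2] == m[1] + 1
            and not (self.ins_after[i0] or self.ins_after[i0 + 1])
        ):
            return self.read[m[0] : m[0] + 3]
        return None

    _RESCUE_WINDOW = 15

    def _diagonal_codon(self, i0: int) -> str | None:
        """Codon read off the alignment diagonal voted by flanking anchors.

        Anchored bases within a window on each side of the codon vote with
        their diagonal (read position minus reference position); the codon
        is read at the best diagonal present on *both* sides.  A genuine
        indel between the flanks leaves no shared diagonal, returning None.
        """
        n = len(self.ref_to_read)
        lo = max(i0 - self._RESCUE_WINDOW, 0)
        hi = min(i0 + 3 + self._RESCUE_WINDOW, n)
        left_diags: dict[int, int] = {}
        right_diags: dict[int, int] = {}
        for i in range(lo, i0):
            if self.ref_to_read[i] >= 0:
                d = int(self.ref_to_read[i]) - i
                left_diags[d] = left_diags.get(d, 0) + 1
        for i in range(i0 + 3, hi):
            if self.ref_to_read[i] >= 0:
                d = int(self.ref_to_read[i]) - i
                right_diags[d] = right_diags.get(d, 0) + 1
        shared = set(left_diags) & set(right_diags)
        if not shared:
            return None
        d = max(shared, key=lambda k: (left_diags[k] + right_diags[k], -k))
        q0 = d + i0
        if q0 < 0 or q0 + 3 > len(self.read):
            return None
        return self.read[q0 : q0 + 3]


@dataclass
class VariantGenotype:
    """The designed mutations carried by one library member."""

    mutations: tuple[str, ...]
    support: int = 1

    def __post_init__(self) -> None:
        if self.support < 1:
            raise ValueError("support must be >= 1")
        self.mutations = tuple(sorted(self.mutations))


@dataclass
class LibraryStats:
    """Diversity summary of a genotyped read set.

    Mean mutation load is averaged over *unique* variants, not reads.
    """

    total_reads: int
    passing_reads: int
    unique_variants: int
    mean_mutation_load: float
    counts: pd.DataFrame  # mutation_id, mut, wt, other

    def to_dict(self) -> dict:
        return {
            "total_reads": self.total_reads,
            "passing_reads": self.passing_reads,
            "unique_variants": self.unique_variants,
            "mean_mutation_load": self.mean_mutation_load,
        }


def _align_oriented(read: str, reference: str):
    fwd = edlib.align(read, reference, mode="HW", task="distance")
    rc = revcomp(read)
    rev = edlib.align(rc, reference, mode="HW", task="distance")
    if rev["editDistance"] < fwd["editDistance"]:
        return rc, "-"
    return read, "+"


def filter_full_length(
    read: str,
    reference: str,
    min_coverage: float = 0.95,
    min_identity: float = 0.85,
    read_id: str = "read",
) -> ReadAlignment | None:
    """Semi-global alignment of a read to the reference CDS, or None.

    The read is accepted only if the aligned reference span covers at least
    ``min_coverage`` of the CDS with identity at least ``min_identity``.
    Reverse-complement orientation is auto-detected.
    """
    read = read.upper()
    reference = reference.upper()
    if not is_dna(read) or not is_dna(reference):
        raise ValueError("sequences must be DNA (ACGTN)")
    oriented, strand = _align_oriented(read, reference)
    infix = edlib.align(oriented, reference, mode="HW", task="locations")
    if infix["editDistance"] < 0 or not infix["locations"]:
        return None
    ref_start, ref_end_incl = infix["locations"][0]
    ref_end = ref_end_incl + 1
    span = ref_end - ref_start
    coverage = span / len(reference)
    identity = 1.0 - infix["editDistance"] / max(len(oriented), span)
    if coverage < min_coverage or identity < min_identity:
        return None

    # coordinates from the global alignment: pinned ends keep the codon
    # frame honest (the infix mode may clip a reference end to dodge an
    # edge mismatch, shifting the frame of edge codons)
    aln = edlib.align(oriented, reference, mode="NW", task="path")
    ref_to_read = np.full(len(reference), -1, dtype=np.int64)
    ins_after = np.zeros(len(reference), dtype=bool)
    t, q = 0, 0
    for count, op in _CIGAR_RE.findall(aln["cigar"]):
        n = int(count)
        if op in "=XM":
            ref_to_read[t : t + n] = np.arange(q, q + n)
            t += n
            q += n
        elif op == "I":  # read bases absent from the reference
            if t > 0:
                ins_after[t - 1] = True
            q += n
        elif op == "D":  # reference bases absent from the read
            t += n
    return ReadAlignment(
        read_id=read_id,
        read=oriented,
        strand=strand,
        ref_start=ref_start,
        ref_end=ref_end,
        identity=identity,
        coverage=coverage,
        ref_to_read=ref_to_read,
        ins_after=ins_after,
    )


def call_genotype(
    alignment: ReadAlignment, design: MutationLibraryDesign
) -> tuple[VariantGenotype, dict[str, str]]:
    """Scan every designed codon position of an aligned read.

    Returns the genotype (set of MUT ids) and the per-mutation state map
    (``WT`` / ``MUT`` / ``OTHER``).
    """
    states: dict[str, str] = {}
    muts: list[str] = []
    for m in design.mutations:
        codon = alignment.codon(m.aa_pos)
        if codon == m.wt_codon:
            states[m.mutation_id] = "WT"
        elif codon == m.mut_codon:
            states[m.mutation_id] = "MUT"
            muts.append(m.mutation_id)
        else:
            states[m.mutation_id] = "OTHER"
    return VariantGenotype(tuple(muts)), states


@dataclass
class GenotypingResult:
    """Per-read table plus aggregate per-mutation counts."""

    table: pd.DataFrame
    counts: pd.DataFrame
    genotypes: list[tuple[str, ...]] = field(default_factory=list)

    @property
    def total_reads(self) -> int:
        return len(self.table)

    @property
    def passing_reads(self) -> int:
        return int(self.table["passed"].sum())


def genotype_reads(
    reads: Iterable[tuple[str, str]],
    design: MutationLibraryDesign,
    min_coverage: float = 0.95,
    min_identity: float = 0.85,
) -> GenotypingResult:
    """Filter, align and genotype a read set against the design.

    ``reads`` is an iterable of ``(read_id, sequence)``.
    """
    ids = design.ids
    col = {m: i for i, m in enumerate(ids)}
    tallies = np.zeros((len(ids), 3), dtype=np.int64)  # WT, MUT, OTHER
    rows = []
    genotypes: list[tuple[str, ...]] = []
    state_code = {"WT": 0, "MUT": 1, "OTHER": 2}
    for read_id, seq in reads:
        aln = filter_full_length(seq, design.reference_cds, min_coverage, min_identity, read_id)
        if aln is None:
            rows.append((read_id, False, "", np.nan, np.nan, "", 0))
            continue
        geno, states = call_genotype(aln, design)
        for mid, st in states.items():
            tallies[col[mid], state_code[st]] += 1
        genotypes.append(geno.mutations)
        rows.append(
            (
                read_id,
                True,
                aln.strand,
                round(aln.identity, 6),
                round(aln.coverage, 6),
                ";".join(geno.mutations),
                sum(1 for s in states.values() if s == "OTHER"),
            )
        )
    table = pd.DataFrame(
        rows,
        columns=["read_id", "passed", "strand", "identity", "coverage", "genotype", "n_other"],
    )
    counts = pd.DataFrame(
        {"mutation_id": ids, "wt": tallies[:, 0], "mut": tallies[:, 1], "other": tallies[:, 2]}
    )[["mutation_id", "mut", "wt", "other"]]
    return GenotypingResult(table=table, counts=counts, genotypes=genotypes)


def library_stats(
    genotypes: Iterable[tuple[str, ...]],
    total_reads: int | None = None,
    counts: pd.DataFrame | None = None,
) -> LibraryStats:
    """Library diversity statistics over genotyped reads.

    Unique variants are keyed by exact genotype-set equality; mean mutation
    load is the average over unique variants.  Empty input yields zeros.
    """
    support = Counter(tuple(sorted(g)) for g in genotypes)
    n_pass = sum(support.values())
    uniques = list(support)
    mean_load = float(np.mean([len(g) for g in uniques])) if uniques else 0.0
    if counts is None:
        counts = pd.DataFrame(columns=["mutation_id", "mut", "wt", "other"])
    return LibraryStats(
        total_reads=n_pass if total_reads is None else total_reads,
        passing_reads=n_pass,
        unique_variants=len(uniques),
        mean_mutation_load=mean_load,
        counts=counts,
    )


def variant_abundance(genotypes: Iterable[tuple[str, ...]]) -> pd.DataFrame:
    """Unique variants with read support, most abundant first."""
    support = Counter(tuple(sorted(g)) for g in genotypes)
    rows = [
        (";".join(g), len(g), n)
        for g, n in sorted(support.items(), key=lambda kv: (-kv[1], kv[0]))
    ]
    return pd.DataFrame(rows, columns=["genotype", "load", "support"])


def tally_counts(sample, design: MutationLibraryDesign) -> pd.DataFrame:
    """Per-mutation mut/wt read counts of a population sample, tallied at
    the genotype-ledger level (equivalent to scanning error-free reads)."""
    ids = design.ids
    col = {m: i for i, m in enumerate(ids)}
    G = np.zeros((len(sample.genotypes), len(ids)), dtype=np.int64)
    for vi, g in enumerate(sample.genotypes):
        for mid in g:
            G[vi, col[mid]] = 1
    per_variant = np.bincount(sample.variant_indices, minlength=len(sample.genotypes))
    mut = per_variant @ G
    return pd.DataFrame(
        {"mutation_id": ids, "mut": mut, "wt": sample.n_reads - mut, "other": 0}
    )


def combinatorial_space(n_mutations: int, max_load: int | str) -> int:
    """Number of distinct variants carrying 1..max_load designed mutations.

    Exact integer arithmetic: sum of binomial coefficients C(n, k) for k in
    1..max_load; ``max_load="all"`` gives 2**n - 1.
    """
    if n_mutations < 0:
        raise ValueError("n_mutations must be >= 0")
    if max_load == "all":
        return 2**n_mutations - 1
    if not isinstance(max_load, int) or max_load < 0:
        raise ValueError("max_load must be a non-negative integer or 'all'")
    if max_load > n_mutations:
        raise ValueError("max_load exceeds n_mutations")
    return sum(math.comb(n_mutations, k) for k in range(1, max_load + 1))
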