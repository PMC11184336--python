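"""Synthetic data generators for the whole pipeline, with ground truth.

The generators emulate the experimental workflow of a transposase
directed-evolution screen:

* a shuffled variant library in which each cDNA carries a random subset of
  the designed codon substitutions (zero-truncated Poisson mutation load);
* high-accuracy long reads over full-length variant cDNAs, with i.i.d.
  substitution errors;
* a selection step in which sampling weight grows exponentially with the sum
  of per-mutation activity effects (additive on a log scale), emulating
  sorting cells by transposition activity;
* transposon insertions with target-site duplications (TSDs) into a small
  annotated genome, read out as ITR-anchored junction reads.

Every generator is deterministic per seed: sub-generators derive independent
streams from the master seed by pairing it with a CRC32 hash of a stream
label, so adding a generator never perturbs the others.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.optimize import brentq
from scipy.stats import poisson

from tnevolve._seq import AA_TO_CODONS, AMINO_ACIDS, STOP_CODONS, revcomp, translate
from tnevolve.annotation import Annotation, Transcript
from tnevolve.design import DesignedMutation, MutationLibraryDesign
from tnevolve.io import Record

#: Default ITR-terminal probe used as the junction anchor (hAT-style terminus).
DEFAULT_ITR_PROBE = "CAGTGACGAAAATCTTGTTCACAGTGACGT"

_BASES = np.frombuffer(b"ACGT", dtype="S1")


def _rng(seed: int, stream: str) -> np.random.Generator:
    """Independent stream per (seed, label); label hashed with CRC32."""
    return np.random.default_rng([seed & 0x7FFFFFFF, zlib.crc32(stream.encode())])


@dataclass
class SimulationConfig:
    """Knobs of the library/selection simulation.

    Defaults describe the screening conditions the pipeline is meant for: a
    realized mean mutation load of 4.4 designed substitutions per cDNA,
    CCS-grade reads (substitution error 1e-3, no indels), and 8-bp TSDs.
    """

    seed: int = 0
    read_error_rate: float = 1e-3
    mean_mutation_load: float = 4.4
    n_variants: int = 10_000
    n_reads_naive: int = 200_000
    n_reads_sorted: int = 200_000
    selection_stringency: float = 1.0
    tsd_length: int = 8
    itr_probe: str = DEFAULT_ITR_PROBE
    indel_rate: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.read_error_rate <= 1.0:
            raise ValueError("read_error_rate must be in [0, 1]")
        if not 0.0 <= self.indel_rate <= 1.0:
            raise ValueError("indel_rate must be in [0, 1]")
        if self.mean_mutation_load < 1.0:
            raise ValueError("mean_mutation_load must be >= 1 (loads are zero-truncated)")
        for name in ("n_variants", "n_reads_naive", "n_reads_sorted", "tsd_length"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.selection_stringency < 0:
            raise ValueError("selection_stringency must be >= 0")
        if not self.itr_probe or set(self.itr_probe) - set("ACGT"):
            raise ValueError("itr_probe must be a non-empty ACGT string")


@dataclass(frozen=True)
class TrueInsertion:
    """A planted transposon insertion: 0-based between-base point, strand of
    the transposon orientation, and the duplicated target sequence."""

    contig: str
    point: int
    strand: str
    tsd: str


@dataclass
class GroundTruth:
    """Simulation ledger: what was actually planted, for parameter recovery.

    ``genotypes[i]`` is the tuple of designed-mutation ids carried by variant
    ``i``; ``effects`` maps mutation id to its additive log-scale activity
    effect; ``insertions`` lists planted integration sites.
    """

    genotypes: list[tuple[str, ...]] = field(default_factory=list)
    effects: dict[str, float] = field(default_factory=dict)
    insertions: list[TrueInsertion] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "genotypes": [list(g) for g in self.genotypes],
            "effects": self.effects,
            "insertions": [
                {"contig": s.contig, "point": s.point, "strand": s.strand, "tsd": s.tsd}
                for s in self.insertions
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        d = json.loads(Path(path).read_text())
        return cls(
            genotypes=[tuple(g) for g in d.get("genotypes", [])],
            effects=dict(d.get("effects", {})),
            insertions=[TrueInsertion(**s) for s in d.get("insertions", [])],
        )


# --------------------------------------------------------------------------
# Reference and design
# --------------------------------------------------------------------------


def make_reference(length_aa: int, seed: int) -> tuple[str, str]:
    """Random reference CDS and its translation.

    The protein starts with M; each codon is drawn uniformly among the
    synonymous codons of its residue, and one stop codon is appended, so the
    CDS is ``3 * length_aa + 3`` nt.
    """
    if length_aa < 10:
        raise ValueError("length_aa must be >= 10")
    rng = _rng(seed, "reference")
    protein = "M" + "".join(rng.choice(list(AMINO_ACIDS), size=length_aa - 1))
    codons = [rng.choice(AA_TO_CODONS[aa]) for aa in protein]
    codons.append(rng.choice(STOP_CODONS))
    cds = "".join(codons)
    assert translate(cds) == protein + "*"
    return cds, protein


def make_design(reference_cds: str, n_mutations: int, seed: int) -> MutationLibraryDesign:
    """Draw a catalogue of designed codon substitutions.

    At most one designed mutation per codon position; the start codon is
    never mutated.  Each substitution changes the amino acid, and the
    replacement codon is drawn uniformly among codons of the new residue.
    Mutation ids use the ``<wt><pos><mut>`` convention (e.g. ``V356L``).
    """
    if n_mutations < 0:
        raise ValueError("n_mutations must be >= 0")
    protein = translate(reference_cds).rstrip("*")
    eligible = list(range(2, len(protein) + 1))  # skip the start codon
    if n_mutations > len(protein):
        raise ValueError(
            f"n_mutations={n_mutations} exceeds codon count {len(protein)}"
        )
    if n_mutations > len(eligible):
        raise ValueError("n_mutations exceeds mutable codon count")
    rng = _rng(seed, "design")
    positions = sorted(rng.choice(eligible, size=n_mutations, replace=False))
    mutations = []
    for pos in positions:
        wt_aa = protein[pos - 1]
        mut_aa = rng.choice([a for a in AMINO_ACIDS if a != wt_aa])
        mutations.append(
            DesignedMutation(
                mutation_id=f"{wt_aa}{pos}{mut_aa}",
                aa_pos=int(pos),
                wt_aa=wt_aa,
                mut_aa=mut_aa,
                wt_codon=reference_cds[3 * (pos - 1) : 3 * pos],
                mut_codon=rng.choice(AA_TO_CODONS[mut_aa]),
            )
        )
    return MutationLibraryDesign(reference_cds=reference_cds, mutations=mutations)


# --------------------------------------------------------------------------
# Library and selection
# --------------------------------------------------------------------------


def _ztp_rate(mean: float) -> float:
    """Rate of the zero-truncated Poisson with the given mean (> 1)."""
    if mean <= 1.0:
        return 0.0
    return brentq(lambda lam: lam / (1.0 - np.exp(-lam)) - mean, max(1e-12, mean - 1.0), mean)


def _sample_ztp(mean: float, size: int, rng: np.random.Generator) -> np.ndarray:
    lam = _ztp_rate(mean)
    if lam == 0.0:
        return np.ones(size, dtype=np.int64)
    draws = rng.poisson(lam, size=size)
    while True:
        zeros = draws == 0
        if not zeros.any():
            return draws
        draws[zeros] = rng.poisson(lam, size=int(zeros.sum()))


def variant_sequence(design: MutationLibraryDesign, genotype: tuple[str, ...]) -> str:
    """The full CDS of a variant carrying the given designed mutations."""
    seq = list(design.reference_cds)
    for mid in genotype:
        m = design.by_id(mid)
        i = 3 * (m.aa_pos - 1)
        seq[i : i + 3] = m.mut_codon
    return "".join(seq)


def _add_errors(seq: str, error_rate: float, rng: np.random.Generator) -> str:
    if error_rate <= 0:
        return seq
    n_err = rng.binomial(len(seq), error_rate)
    if n_err == 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    pos = rng.choice(len(seq), size=n_err, replace=False)
    for p in pos:
        choices = _BASES[_BASES != arr[p]]
        arr[p] = rng.choice(choices)
    return arr.tobytes().decode()


def sample_genotypes(
    design: MutationLibraryDesign, config: SimulationConfig
) -> list[tuple[str, ...]]:
    """Draw the unique-variant genotype list: loads are zero-truncated
    Poisson with mean ``mean_mutation_load`` (capped at the catalogue size),
    mutation subsets uniform without replacement."""
    rng = _rng(config.seed, "genotypes")
    ids = np.array(design.ids)
    loads = np.minimum(_sample_ztp(config.mean_mutation_load, config.n_variants, rng), len(ids))
    return [
        tuple(sorted(rng.choice(ids, size=int(k), replace=False))) for k in loads
    ]


@dataclass
class PopulationSample:
    """Reads sampled from a variant population, kept as variant draws.

    ``variant_indices[j]`` is the variant each read was drawn from.
    Sequences are materialized lazily (:meth:`reads`) so large screens can be
    tallied at the genotype level without holding gigabases in memory.
    """

    name: str
    variant_indices: np.ndarray
    genotypes: list[tuple[str, ...]]

    @property
    def n_reads(self) -> int:
        return int(self.variant_indices.size)

    def reads(
        self,
        design: MutationLibraryDesign,
        error_rate: float = 0.0,
        seed: int = 0,
    ):
        """Yield ``(read_id, sequence)`` with i.i.d. substitution errors."""
        rng = _rng(seed, f"reads:{self.name}")
        cache: dict[int, str] = {}
        for j, vi in enumerate(self.variant_indices):
            vi = int(vi)
            if vi not in cache:
                cache[vi] = variant_sequence(design, self.genotypes[vi])
            yield f"{self.name}_{j}", _add_errors(cache[vi], error_rate, rng)

    def write_fastq(
        self,
        path: str | Path,
        design: MutationLibraryDesign,
        error_rate: float = 0.0,
        seed: int = 0,
    ) -> None:
        from tnevolve.io import write_fastq

        write_fastq(self.reads(design, error_rate, seed), path)


def simulate_library(
    design: MutationLibraryDesign,
    config: SimulationConfig,
    n_reads: int | None = None,
) -> tuple[GroundTruth, PopulationSample]:
    """Simulate the naive (preselection) library.

    Returns the ground truth (unique-variant genotypes) and a uniform read
    sample over variants; ``n_reads`` defaults to ``config.n_reads_naive``.
    """
    genotypes = sample_genotypes(design, config)
    n = config.n_reads_naive if n_reads is None else n_reads
    rng = _rng(config.seed, "library-draws")
    draws = rng.integers(0, len(genotypes), size=n) if genotypes else np.empty(0, dtype=np.int64)
    truth = GroundTruth(genotypes=genotypes)
    return truth, PopulationSample("naive", draws, genotypes)


def selection_weights(
    genotypes: list[tuple[str, ...]],
    effects: dict[str, float],
    stringency: float,
) -> np.ndarray:
    """Sampling weight per variant: ``exp(stringency * sum of effects)``."""
    score = np.array(
        [sum(effects.get(mid, 0.0) for mid in g) for g in genotypes], dtype=float
    )
    w = np.exp(stringency * score)
    return w / w.sum()


def simulate_sort(
    genotypes: list[tuple[str, ...]],
    effects: dict[str, float],
    config: SimulationConfig,
    seed: int | None = None,
) -> tuple[PopulationSample, PopulationSample]:
    """Sample naive and sorted read populations from one variant library.

    Naive reads are uniform over variants; sorted reads are drawn with
    weight proportional to ``exp(selection_stringency * sum(effects))`` —
    the additive log-scale activity model of the selection step.
    """
    if not genotypes:
        raise ValueError("genotype list is empty")
    seed = config.seed if seed is None else seed
    rng = _rng(seed, "sort")
    naive = rng.integers(0, len(genotypes), size=config.n_reads_naive)
    weights = selection_weights(genotypes, effects, config.selection_stringency)
    sorted_draws = rng.choice(len(genotypes), size=config.n_reads_sorted, p=weights)
    return (
        PopulationSample("naive", naive, genotypes),
        PopulationSample("sorted", sorted_draws, genotypes),
    )


def moi_copy_distribution(moi: float) -> dict[str, float]:
    """Poisson copy-number probabilities at a given multiplicity of
    infection: P(0 copies), P(1 copy), P(>= 2 copies)."""
    if moi < 0:
        raise ValueError("moi must be >= 0")
    p0 = float(poisson.pmf(0, moi))
    p1 = float(poisson.pmf(1, moi))
    return {"0": p0, "1": p1, "2+": 1.0 - p0 - p1}


# --------------------------------------------------------------------------
# Genome, insertions, junction reads
# --------------------------------------------------------------------------


@dataclass
class GenomeSimulation:
    """Bundle returned by :func:`simulate_genome_and_insertions`."""

    genome: dict[str, str]
    annotation: Annotation
    truth: GroundTruth
    junction_reads: list[Record]


def _split_lengths(
    total: int, parts: int, min_len: int, rng: np.random.Generator
) -> list[int]:
    """Split ``total`` into ``parts`` lengths >= min_len, randomly."""
    slack = total - parts * min_len
    if slack < 0:
        raise ValueError("total too small for requested parts")
    cuts = np.sort(rng.integers(0, slack + 1, size=parts - 1)) if parts > 1 else np.array([], dtype=int)
    pieces = np.diff(np.concatenate([[0], cuts, [slack]]))
    return [int(min_len + p) for p in pieces]


def _random_genome(length: int, rng: np.random.Generator) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode()


def _place_genes(
    contig: str,
    length: int,
    transcript_fraction: float,
    rng: np.random.Generator,
) -> list[Transcript]:
    """Tile genes left to right with random intergenic gaps until the target
    transcript fraction is reached.  Exons cover ~65% of the gene span; the
    central ~80% of spliced bases is CDS, the rest UTR."""
    transcripts = []
    cursor = 0
    covered = 0
    k = 0
    while covered < transcript_fraction * length:
        gap = int(rng.integers(6_000, 18_000))
        gene_len = int(rng.integers(3_000, 10_001))
        start = cursor + gap
        end = start + gene_len
        if end >= length - 1_000:
            break
        n_exons = int(rng.integers(2, 7))
        exon_total = int(gene_len * rng.uniform(0.55, 0.75))
        exon_lens = _split_lengths(exon_total, n_exons, 80, rng)
        intron_lens = _split_lengths(gene_len - exon_total, n_exons - 1, 60, rng)
        exons = []
        pos = start
        for i, el in enumerate(exon_lens):
            exons.append((pos, pos + el))
            pos += el
            if i < len(intron_lens):
                pos += intron_lens[i]
        # trim/extend last exon so the gene ends exactly at `end`
        exons[-1] = (exons[-1][0], end)
        spliced = sum(e - s for s, e in exons)
        utr = max(1, int(0.10 * spliced))
        cds = _spliced_slice(exons, utr, spliced - utr)
        strand = "+" if rng.random() < 0.5 else "-"
        transcripts.append(
            Transcript(f"{contig}.tx{k}", contig, start, end, strand, exons, cds)
        )
        covered += end - start
        cursor = end
        k += 1
    return transcripts


def _spliced_slice(
    exons: list[tuple[int, int]], sp_start: int, sp_end: int
) -> list[tuple[int, int]]:
    """Map a spliced-coordinate interval back to genomic exon intervals."""
    out = []
    offset = 0
    for s, e in exons:
        el = e - s
        lo = max(sp_start - offset, 0)
        hi = min(sp_end - offset, el)
        if hi > lo:
            out.append((s + lo, s + hi))
        offset += el
    return out


def simulate_genome_and_insertions(
    config: SimulationConfig,
    seed: int | None = None,
    *,
    genome_length: int = 2_000_000,
    n_contigs: int = 2,
    transcript_fraction: float = 0.30,
    n_insertions: int = 500,
    flank_length: int = 50,
    reads_per_junction: int = 2,
    tss_bias: float = 0.0,
    tss_bias_scale: float = 5_000.0,
    vector_read_fraction: float = 0.05,
) -> GenomeSimulation:
    """Simulate an annotated toy genome, transposon insertions, and
    ITR-anchored junction reads.

    Each insertion at between-base point ``p`` duplicates the target
    ``tsd_length``-mer ``genome[p : p + L]`` on both sides of the element.
    Per side, ``reads_per_junction`` reads are emitted, each the ITR probe
    followed by ``flank_length`` bases of flanking genome (the left-side
    flank reads outward on the minus strand).  With ``tss_bias > 0`` that
    fraction of insertions is placed near a random TSS at an exponential
    offset (scale ``tss_bias_scale``); otherwise placement is uniform.
    A fraction of transposon-internal ("vector-only") reads carrying no
    genomic sequence is mixed in to exercise junction filtering.
    """
    seed = config.seed if seed is None else seed
    rng = _rng(seed, "genome")
    L = config.tsd_length
    contig_len = genome_length // n_contigs
    genome = {f"chr{i + 1}": _random_genome(contig_len, rng) for i in range(n_contigs)}
    transcripts: list[Transcript] = []
    for contig in genome:
        transcripts.extend(_place_genes(contig, contig_len, transcript_fraction, rng))
    annotation = Annotation(transcripts)

    lo = flank_length
    hi = contig_len - flank_length - L
    if hi <= lo:
        raise ValueError("contigs too short for the requested flank and TSD lengths")
    avail = n_contigs * (hi - lo)
    if n_insertions > avail // 100:
        raise ValueError("insertion count exceeds available positions")

    contigs = sorted(genome)
    all_tss = [(c, int(t)) for c in contigs for t in annotation.tss_positions(c)]
    taken: dict[str, list[int]] = {c: [] for c in contigs}
    sites: list[TrueInsertion] = []
    ins_rng = _rng(seed, "insertions")
    while len(sites) < n_insertions:
        if all_tss and ins_rng.random() < tss_bias:
            contig, tss = all_tss[int(ins_rng.integers(len(all_tss)))]
            offset = int(ins_rng.exponential(tss_bias_scale)) * (1 if ins_rng.random() < 0.5 else -1)
            p = int(np.clip(tss + offset, lo, hi - 1))
        else:
            contig = contigs[int(ins_rng.integers(n_contigs))]
            p = int(ins_rng.integers(lo, hi))
        if any(abs(p - q) < 50 for q in taken[contig]):
            continue
        taken[contig].append(p)
        strand = "+" if ins_rng.random() < 0.5 else "-"
        sites.append(TrueInsertion(contig, p, strand, genome[contig][p : p + L]))
    sites.sort(key=lambda s: (s.contig, s.point))

    probe = config.itr_probe
    read_rng = _rng(seed, "junction-reads")
    reads: list[Record] = []
    for i, s in enumerate(sites):
        g = genome[s.contig]
        right = probe + g[s.point : s.point + flank_length]
        left = probe + revcomp(g[s.point + L - flank_length : s.point + L])
        for r in range(reads_per_junction):
            reads.append(
                (f"jr{i}R{r}", _add_errors(right, config.read_error_rate, read_rng))
            )
            reads.append(
                (f"jr{i}L{r}", _add_errors(left, config.read_error_rate, read_rng))
            )
    # transposon-internal reads: windows of the element body, no genomic part
    vector_body = probe + _random_genome(500, _rng(seed, "vector")) + revcomp(probe)
    n_vec = int(round(vector_read_fraction * len(reads))) if sites else 0
    for j in range(n_vec):
        win = int(read_rng.integers(0, 40))
        reads.append(
            (
                f"vec{j}",
                _add_errors(
                    probe + vector_body[len(probe) + win : len(probe) + win + flank_length],
                    config.read_error_rate,
                    read_rng,
                ),
            )
        )
    truth = GroundTruth(insertions=sites)
    return GenomeSimulation(genome, annotation, truth, reads)


# --------------------------------------------------------------------------
# Protein MSA with planted candidates
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class PlantedCandidate:
    """A planted candidate substitution: target residue at 1-based target
    position, and the conserved consensus residue it should be changed to."""

    position: int
    target_aa: str
    consensus_aa: str

    @property
    def label(self) -> str:
        return f"{self.target_aa}{self.position}{self.consensus_aa}"


def simulate_msa(
    n_seqs: int,
    n_candidate_positions: int,
    conservation: float,
    seed: int,
    n_columns: int = 120,
    target_id: str = "target",
    background_noise: float = 0.05,
) -> tuple[list[Record], list[PlantedCandidate]]:
    """Simulate a protein alignment with planted candidate positions.

    At each planted column the target carries a residue that differs from a
    consensus shared by at least ``conservation`` of the non-target rows (the
    guarantee is by construction: exactly ``ceil(conservation * (n_seqs-1))``
    rows carry it, the rest carry other residues).  Elsewhere the target
    matches the background consensus, which other rows deviate from at rate
    ``background_noise``.  The target row has no gaps, so target numbering
    equals column numbering.
    """
    if n_seqs < 2:
        raise ValueError("n_seqs must be >= 2")
    if not 0.0 <= conservation <= 1.0:
        raise ValueError("conservation must be in [0, 1]")
    if n_candidate_positions > n_columns:
        raise ValueError("n_candidate_positions exceeds alignment length")
    rng = _rng(seed, "msa")
    aas = list(AMINO_ACIDS)
    consensus = rng.choice(aas, size=n_columns)
    planted_cols = sorted(rng.choice(n_columns, size=n_candidate_positions, replace=False))
    n_other = n_seqs - 1
    n_conserved = int(np.ceil(conservation * n_other))

    rows = {target_id: list(consensus)}
    others = [f"homolog_{i}" for i in range(n_other)]
    for name in others:
        row = list(consensus)
        for c in range(n_columns):
            if c in planted_cols:
                continue
            r = rng.random()
            if r < background_noise / 2:
                row[c] = "-"
            elif r < background_noise:
                row[c] = rng.choice(aas)
        rows[name] = row

    planted: list[PlantedCandidate] = []
    for c in planted_cols:
        target_aa = consensus[c]
        cons_aa = rng.choice([a for a in aas if a != target_aa])
        which = rng.permutation(n_other)
        for k, idx in enumerate(which):
            if k < n_conserved:
                rows[others[idx]][c] = cons_aa
            else:
                rows[others[idx]][c] = rng.choice(
                    [a for a in aas if a not in (cons_aa, target_aa)]
                )
        planted.append(PlantedCandidate(position=c + 1, target_aa=target_aa, consensus_aa=cons_aa))

    records = [(target_id, "".join(rows[target_id]))]
    records += [(name, "".join(rows[name])) for name in others]
    return records, planted
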