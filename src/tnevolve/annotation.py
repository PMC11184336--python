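"""Transcript annotation model with TSS and genomic-context indexes.

Coordinates are 0-based half-open internally; GFF3 is written and read
1-based inclusive per the standard.  A transcription start site (TSS) is the
strand-aware 5' base of a transcript: ``start`` on the plus strand,
``end - 1`` on the minus strand.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import gffutils
import numpy as np
from intervaltree import IntervalTree


@dataclass
class Transcript:
    """One transcript: genomic span, strand, exon and CDS intervals.

    ``exons`` and ``cds`` are lists of 0-based half-open ``(start, end)``
    intervals in genomic coordinates.
    """

    transcript_id: str
    contig: str
    start: int
    end: int
    strand: str
    exons: list[tuple[int, int]] = field(default_factory=list)
    cds: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"{self.transcript_id}: strand must be + or -")
        if not 0 <= self.start < self.end:
            raise ValueError(f"{self.transcript_id}: invalid span")

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1


def _merged_length(intervals: list[tuple[int, int]]) -> int:
    total, prev_end = 0, -1
    for s, e in sorted(intervals):
        s = max(s, prev_end)
        if e > s:
            total += e - s
            prev_end = e
        prev_end = max(prev_end, e)
    return total


class Annotation:
    """Indexed collection of transcripts supporting the profiling queries:
    nearest-TSS distance and context classification (CDS exon > transcript)."""

    def __init__(self, transcripts: list[Transcript]):
        self.transcripts = list(transcripts)
        self._tss: dict[str, np.ndarray] = {}
        self._tx_tree: dict[str, IntervalTree] = {}
        self._cds_tree: dict[str, IntervalTree] = {}
        by_contig: dict[str, list[Transcript]] = {}
        for tx in self.transcripts:
            by_contig.setdefault(tx.contig, []).append(tx)
        for contig, txs in by_contig.items():
            self._tss[contig] = np.array(sorted({t.tss for t in txs}), dtype=np.int64)
            tx_tree = IntervalTree()
            cds_tree = IntervalTree()
            for t in txs:
                tx_tree.addi(t.start, t.end)
                for s, e in t.cds:
                    if e > s:
                        cds_tree.addi(s, e)
            self._tx_tree[contig] = tx_tree
            self._cds_tree[contig] = cds_tree

    @property
    def contigs(self) -> list[str]:
        return sorted(self._tss)

    def has_contig(self, contig: str) -> bool:
        return contig in self._tss

    def tss_positions(self, contig: str) -> np.ndarray:
        return self._tss.get(contig, np.empty(0, dtype=np.int64))

    def nearest_tss_distance(self, contig: str, point: int) -> int:
        """Unsigned distance (bases) from ``point`` to the nearest TSS of any
        transcript on ``contig``."""
        tss = self._tss.get(contig)
        if tss is None or tss.size == 0:
            raise KeyError(f"contig {contig!r} has no annotated transcripts")
        i = int(np.searchsorted(tss, point))
        best = np.inf
        for j in (i - 1, i):
            if 0 <= j < tss.size:
                best = min(best, abs(int(tss[j]) - point))
        return int(best)

    def context(self, contig: str, point: int) -> str:
        """Classify a genomic point: ``coding_exon`` if inside any CDS exon,
        else ``transcript_noncoding`` if inside any transcript, else
        ``outside_transcript``.  Precedence is fixed in that order."""
        if contig in self._cds_tree and self._cds_tree[contig].overlaps(point):
            return "coding_exon"
        if contig in self._tx_tree and self._tx_tree[contig].overlaps(point):
            return "transcript_noncoding"
        return "outside_transcript"

    def transcript_bp(self) -> int:
        """Union of transcript spans in bases, per-contig overlaps merged."""
        total = 0
        by_contig: dict[str, list[tuple[int, int]]] = {}
        for t in self.transcripts:
            by_contig.setdefault(t.contig, []).append((t.start, t.end))
        for ivs in by_contig.values():
            total += _merged_length(ivs)
        return total

    def cds_bp(self) -> int:
        by_contig: dict[str, list[tuple[int, int]]] = {}
        for t in self.transcripts:
            by_contig.setdefault(t.contig, []).extend(t.cds)
        return sum(_merged_length(ivs) for ivs in by_contig.values())

    # ------------------------------------------------------------------ GFF3

    def to_gff3(self, path: str | Path, contig_lengths: dict[str, int] | None = None) -> None:
        lines = ["##gff-version 3"]
        if contig_lengths:
            for contig, length in sorted(contig_lengths.items()):
                lines.append(f"##sequence-region {contig} 1 {length}")
        for t in sorted(self.transcripts, key=lambda t: (t.contig, t.start)):
            gid = f"gene:{t.transcript_id}"
            lines.append(
                f"{t.contig}\ttnevolve\tgene\t{t.start + 1}\t{t.end}\t.\t{t.strand}\t.\tID={gid}"
            )
            lines.append(
                f"{t.contig}\ttnevolve\tmRNA\t{t.start + 1}\t{t.end}\t.\t{t.strand}\t.\t"
                f"ID={t.transcript_id};Parent={gid}"
            )
            for k, (s, e) in enumerate(sorted(t.exons)):
                lines.append(
                    f"{t.contig}\ttnevolve\texon\t{s + 1}\t{e}\t.\t{t.strand}\t.\t"
                    f"ID={t.transcript_id}.exon{k};Parent={t.transcript_id}"
                )
            for k, (s, e) in enumerate(sorted(t.cds)):
                lines.append(
                    f"{t.contig}\ttnevolve\tCDS\t{s + 1}\t{e}\t.\t{t.strand}\t0\t"
                    f"ID={t.transcript_id}.cds;Parent={t.transcript_id}"
                )
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_gff3(cls, path: str | Path) -> "Annotation":
        db = gffutils.create_db(
            str(path),
            dbfn=":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
        )
        transcripts = []
        for feat in db.features_of_type(("mRNA", "transcript")):
            exons = [(c.start - 1, c.end) for c in db.children(feat, featuretype="exon")]
            cds = [(c.start - 1, c.end) for c in db.children(feat, featuretype="CDS")]
            transcripts.append(
                Transcript(
                    transcript_id=feat.id,
                    contig=feat.seqid,
                    start=feat.start - 1,
                    end=feat.end,
                    strand=feat.strand,
                    exons=sorted(exons),
                    cds=sorted(cds),
                )
            )
        return cls(transcripts)
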