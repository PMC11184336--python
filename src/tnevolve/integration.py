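"""Transposon integration-site recovery and safety profiling.

Junction reads (ITR terminus followed by flanking genome) are trimmed to
their genomic portion, mapped by exact search against the genome, clustered
into deduplicated insertion sites (opposite-side junction pairs offset by
exactly the TSD length collapse into one insertion, with the duplicated
target sequence read off the genome), and summarized as a safety profile:
unsigned distance to the nearest transcription start site and a genomic
context class per site, compared against a matched uniform-random baseline.

Coordinates are 0-based; an insertion point is a between-base coordinate
``p`` such that the duplicated target k-mer is ``genome[p : p + L]``.
Plus-strand junction fragments start at ``p``; minus-strand fragments end at
``p + L``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from tnevolve._seq import revcomp
from tnevolve.annotation import Annotation
from tnevolve.io import Record

CONTEXT_CLASSES = ("coding_exon", "transcript_noncoding", "outside_transcript")


@dataclass
class InsertionSite:
    """One deduplicated insertion locus."""

    contig: str
    point: int
    strand: str
    tsd: str
    support: int

    def __post_init__(self) -> None:
        if self.point < 0:
            raise ValueError("insertion point must be >= 0")
        if self.support < 1:
            raise ValueError("support must be >= 1")


# --------------------------------------------------------------------- reads


def extract_junctions(
    reads: Iterable[Record],
    itr_probe: str,
    min_itr_match: int = 12,
    min_genomic_len: int = 20,
) -> list[Record]:
    """Trim ITR-anchored junction reads to their genomic portion.

    A read qualifies when it begins (in either orientation) with at least
    ``min_itr_match`` terminal bases of the probe; the matched prefix is
    trimmed off.  Reads that are transposon over their whole length — i.e.
    whose remainder after trimming is shorter than ``min_genomic_len`` — are
    discarded, as are reads with no probe match.
    """
    if not itr_probe:
        raise ValueError("itr_probe must be non-empty")
    probe = itr_probe.upper()
    out: list[Record] = []
    for read_id, seq in reads:
        seq = seq.upper()
        frag = None
        for oriented in (seq, revcomp(seq)):
            t = _probe_prefix_len(oriented, probe, min_itr_match)
            if t:
                frag = oriented[t:]
                break
        if frag is None or len(frag) < min_genomic_len:
            continue
        out.append((read_id, frag))
    return out


def _probe_prefix_len(seq: str, probe: str, min_match: int) -> int:
    """Length of the longest probe terminus that prefixes ``seq`` (0 if the
    best match is below ``min_match``)."""
    for t in range(len(probe), min_match - 1, -1):
        if seq.startswith(probe[-t:]):
            return t
    return 0


def map_fragments(
    fragments: Iterable[Record],
    genome: dict[str, str],
    max_hits: int = 1,
) -> pd.DataFrame:
    """Place genomic fragments by exact search over both strands.

    Each fragment's junction-proximal base is its first base, so a
    plus-strand hit at index ``i`` gives junction coordinate ``i`` and a
    minus-strand hit ending at index ``j`` gives the between-base coordinate
    ``j + 1``.  Fragments with more than ``max_hits`` placements are flagged
    ``multimap``; fragments with none are ``unmapped``; both are excluded
    from site calling downstream.
    """
    rows = []
    for frag_id, seq in fragments:
        hits = []
        rc = revcomp(seq)
        for contig, chrom in genome.items():
            for query, strand in ((seq, "+"), (rc, "-")):
                start = chrom.find(query)
                while start != -1:
                    if strand == "+":
                        hits.append((contig, start, "+"))
                    else:
                        hits.append((contig, start + len(query), "-"))
                    start = chrom.find(query, start + 1)
                    if len(hits) > max_hits:
                        break
            if len(hits) > max_hits:
                break
        if not hits:
            rows.append((frag_id, "", -1, ".", "unmapped"))
        elif len(hits) > max_hits:
            rows.append((frag_id, "", -1, ".", "multimap"))
        else:
            contig, pos, strand = hits[0]
            rows.append((frag_id, contig, pos, strand, "mapped"))
    return pd.DataFrame(rows, columns=["fragment_id", "contig", "position", "strand", "status"])


def load_loci(path: str | Path) -> pd.DataFrame:
    """Import externally produced mappings (TSV: contig, 1-based leftmost
    position, strand, fragment id) into the internal 0-based locus table."""
    df = pd.read_csv(path, sep="\t")
    required = {"contig", "position", "strand", "fragment_id"}
    if not required <= set(df.columns):
        raise ValueError(f"mapped-loci table needs columns {sorted(required)}")
    out = df.copy()
    out["position"] = out["position"].astype(int) - 1
    out["status"] = "mapped"
    return out[["fragment_id", "contig", "position", "strand", "status"]]


# --------------------------------------------------------------------- sites


def _merge_1d(positions: np.ndarray, supports: np.ndarray, window: int):
    """Merge sorted positions within ``window`` into clusters; the cluster
    position is its support-weighted mode (leftmost on ties)."""
    clusters = []
    start = 0
    for i in range(1, len(positions) + 1):
        if i == len(positions) or positions[i] - positions[i - 1] > window:
            pos = positions[start:i]
            sup = supports[start:i]
            best = {}
            for p, s in zip(pos, sup):
                best[p] = best.get(p, 0) + s
            rep = max(sorted(best), key=lambda p: best[p])
            clusters.append((int(rep), int(sup.sum())))
            start = i
    return clusters


def cluster_sites(
    loci: pd.DataFrame,
    genome: dict[str, str],
    merge_window: int = 5,
    tsd_length: int = 8,
) -> list[InsertionSite]:
    """Deduplicate mapped junction loci into insertion sites.

    Same-strand loci within ``merge_window`` merge with support summed.
    A plus-strand junction cluster at ``p`` and a minus-strand cluster at
    ``p + tsd_length`` are the two sides of one insertion and collapse into
    a single site at ``p``, its TSD read off the genome.  Unpaired clusters
    become single-sided sites (a minus-only cluster at ``q`` implies the
    insertion point ``q - tsd_length``).
    """
    mapped = loci[loci["status"] == "mapped"]
    sites: list[InsertionSite] = []
    for contig, group in mapped.groupby("contig"):
        plus = group[group["strand"] == "+"]["position"].to_numpy()
        minus = group[group["strand"] == "-"]["position"].to_numpy()
        p_clusters = _merge_1d(np.sort(plus), np.ones(len(plus), dtype=int), merge_window)
        m_clusters = _merge_1d(np.sort(minus), np.ones(len(minus), dtype=int), merge_window)
        used_m = set()
        for p, p_sup in p_clusters:
            match = None
            for k, (q, q_sup) in enumerate(m_clusters):
                if k in used_m:
                    continue
                if abs((q - p) - tsd_length) <= merge_window:
                    match = (k, q, q_sup)
                    break
            if match is not None:
                k, q, q_sup = match
                used_m.add(k)
                sites.append(
                    InsertionSite(
                        contig=contig,
                        point=p,
                        strand="+",
                        tsd=genome[contig][p : p + tsd_length],
                        support=p_sup + q_sup,
                    )
                )
            else:
                sites.append(
                    InsertionSite(
                        contig=contig,
                        point=p,
                        strand="+",
                        tsd=genome[contig][p : p + tsd_length],
                        support=p_sup,
                    )
                )
        for k, (q, q_sup) in enumerate(m_clusters):
            if k in used_m:
                continue
            p = max(q - tsd_length, 0)
            sites.append(
                InsertionSite(
                    contig=contig,
                    point=p,
                    strand="-",
                    tsd=genome[contig][p : p + tsd_length],
                    support=q_sup,
                )
            )
    sites.sort(key=lambda s: (s.contig, s.point))
    return sites


def sites_to_bed(sites: list[InsertionSite], path: str | Path) -> None:
    """BED6: name = TSD, score = supporting read count."""
    with open(path, "w") as fh:
        for s in sites:
            fh.write(
                f"{s.contig}\t{s.point}\t{s.point + len(s.tsd)}\t{s.tsd}\t{s.support}\t{s.strand}\n"
            )


# ------------------------------------------------------------------- profile


def distance_to_tss(sites: list[InsertionSite], annotation: Annotation) -> pd.DataFrame:
    """Unsigned distance from each site to the nearest TSS of any transcript.

    Sites on contigs absent from the annotation are flagged (distance NaN)
    and excluded from summaries.
    """
    rows = []
    for s in sites:
        if annotation.has_contig(s.contig) and annotation.tss_positions(s.contig).size:
            d = annotation.nearest_tss_distance(s.contig, s.point)
            rows.append((s.contig, s.point, d, True))
        else:
            rows.append((s.contig, s.point, np.nan, False))
    return pd.DataFrame(rows, columns=["contig", "point", "tss_distance", "annotated"])


def classify_context(site: InsertionSite, annotation: Annotation) -> str:
    """Genomic context of a site with precedence
    coding_exon > transcript_noncoding > outside_transcript."""
    return annotation.context(site.contig, site.point)


def _class_fractions(classes: list[str]) -> dict[str, float]:
    n = len(classes)
    return {c: classes.count(c) / n for c in CONTEXT_CLASSES}


@dataclass
class IntegrationProfile:
    """Safety profile of a site set vs. a uniform-random baseline."""

    n_sites: int
    tss_distances: np.ndarray
    contexts: list[str]
    median_tss_distance: float
    median_tss_distance_se: float | None
    class_fractions: dict[str, float]
    baseline_median_tss_distance: float
    baseline_class_fractions: dict[str, float]
    fraction_ratios: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "n_sites": self.n_sites,
            "median_tss_distance": self.median_tss_distance,
            "median_tss_distance_se": self.median_tss_distance_se,
            "class_fractions": self.class_fractions,
            "baseline_median_tss_distance": self.baseline_median_tss_distance,
            "baseline_class_fractions": self.baseline_class_fractions,
            "fraction_ratios": self.fraction_ratios,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))


def profile_summary(
    sites: list[InsertionSite],
    annotation: Annotation,
    genome: dict[str, str],
    n_random: int = 10_000,
    n_bootstrap: int = 200,
    seed: int = 0,
) -> IntegrationProfile:
    """Summarize TSS distances and context classes against a matched
    uniform-random baseline.

    The baseline draws ``n_random`` positions uniformly over the genome
    (contigs weighted by length) and computes the same statistics.  The
    median TSS distance carries a bootstrap standard error over site
    resamples (``n_bootstrap = 0`` reports it as absent).
    """
    if not sites:
        raise ValueError("site list is empty")
    rng = np.random.default_rng(seed)
    dist_df = distance_to_tss(sites, annotation)
    dists = dist_df.loc[dist_df["annotated"], "tss_distance"].to_numpy(dtype=float)
    if dists.size == 0:
        raise ValueError("no site lies on an annotated contig")
    contexts = [classify_context(s, annotation) for s in sites]
    median = float(np.median(dists))
    se = None
    if n_bootstrap > 0:
        boot = [
            float(np.median(rng.choice(dists, size=dists.size, replace=True)))
            for _ in range(n_bootstrap)
        ]
        se = float(np.std(boot, ddof=1))

    contigs = sorted(genome)
    lengths = np.array([len(genome[c]) for c in contigs], dtype=float)
    picks = rng.choice(len(contigs), size=n_random, p=lengths / lengths.sum())
    rand_dists = []
    rand_classes = []
    for ci in picks:
        contig = contigs[ci]
        pos = int(rng.integers(0, len(genome[contig])))
        rand_classes.append(annotation.context(contig, pos))
        if annotation.has_contig(contig) and annotation.tss_positions(contig).size:
            rand_dists.append(annotation.nearest_tss_distance(contig, pos))
    obs_frac = _class_fractions(contexts)
    base_frac = _class_fractions(rand_classes)
    ratios = {
        c: (obs_frac[c] / base_frac[c]) if base_frac[c] > 0 else float("nan")
        for c in CONTEXT_CLASSES
    }
    return IntegrationProfile(
        n_sites=len(sites),
        tss_distances=dists,
        contexts=contexts,
        median_tss_distance=median,
        median_tss_distance_se=se,
        class_fractions=obs_frac,
        baseline_median_tss_distance=float(np.median(rand_dists)) if rand_dists else float("nan"),
        baseline_class_fractions=base_frac,
        fraction_ratios=ratios,
    )
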