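"""Configured end-to-end pipeline with provenance records.

Stages (``simulate`` -> ``qc`` -> ``enrich``, and ``simulate`` -> ``sites``)
read and write standard formats in one output directory.  Every stage
writes a provenance JSON (parameters, master seed, SHA-256 of its inputs)
sufficient to re-run it in isolation; data outputs are deterministic per
master seed, with floats serialized to 6 significant digits.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from tnevolve import io
from tnevolve.design import MutationLibraryDesign, load_design
from tnevolve.enrichment import enrichment_summary, enrichment_table
from tnevolve.integration import (
    cluster_sites,
    extract_junctions,
    map_fragments,
    profile_summary,
    sites_to_bed,
)
from tnevolve.annotation import Annotation
from tnevolve.qc import genotype_reads, library_stats, variant_abundance
from tnevolve.simulate import (
    SimulationConfig,
    make_design,
    make_reference,
    simulate_genome_and_insertions,
    simulate_sort,
    sample_genotypes,
    _rng,
)

logger = logging.getLogger("tnevolve")

FLOAT_FORMAT = "%.6g"


class ConfigError(ValueError):
    """Unknown or invalid pipeline configuration keys."""


class DependencyError(RuntimeError):
    """A stage input produced by an upstream stage is missing."""


_KNOWN = {
    "seed": None,
    "outdir": None,
    "log_level": None,
    "simulate": {
        "length_aa",
        "n_mutations",
        "n_variants",
        "n_reads_naive",
        "n_reads_sorted",
        "mean_mutation_load",
        "read_error_rate",
        "selection_stringency",
        "n_effect_mutations",
        "effect_size",
        "genome_length",
        "n_contigs",
        "transcript_fraction",
        "n_insertions",
        "tsd_length",
        "tss_bias",
    },
    "qc": {"min_coverage", "min_identity"},
    "enrich": {"pseudocount"},
    "sites": {"min_itr_match", "min_genomic_len", "merge_window", "n_random", "n_bootstrap"},
}


def copy_number(target_concentration: float, reference_concentration: float) -> float:
    """Integrated copies per genome from duplexed ddPCR concentrations:
    fractional abundance adjusted for the two genomic copies of the
    reference locus, i.e. ``2 * target / reference``."""
    if target_concentration < 0:
        raise ValueError("target concentration must be >= 0")
    if reference_concentration <= 0:
        raise ValueError("reference concentration must be > 0")
    return 2.0 * target_concentration / reference_concentration


@dataclass
class PipelineConfig:
    """Validated pipeline configuration (YAML-loadable)."""

    seed: int = 0
    outdir: str = "tnevolve_out"
    log_level: str = "INFO"
    simulate: dict = field(default_factory=dict)
    qc: dict = field(default_factory=dict)
    enrich: dict = field(default_factory=dict)
    sites: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for block in ("simulate", "qc", "enrich", "sites"):
            unknown = set(getattr(self, block)) - _KNOWN[block]
            if unknown:
                raise ConfigError(f"unknown keys in '{block}': {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - set(_KNOWN)
        if unknown:
            raise ConfigError(f"unknown top-level keys: {sorted(unknown)}")
        return cls(**raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _provenance(outdir: Path, stage: str, params: dict, seed: int, inputs: list[Path]) -> None:
    record = {
        "stage": stage,
        "seed": seed,
        "parameters": params,
        "inputs": {p.name: _sha256(p) for p in sorted(inputs) if p.exists()},
    }
    (outdir / f"provenance_{stage}.json").write_text(json.dumps(record, indent=1, sort_keys=True))


def _require(outdir: Path, stage: str, *names: str) -> list[Path]:
    paths = [outdir / n for n in names]
    missing = [p.name for p in paths if not p.exists()]
    if missing:
        raise DependencyError(f"stage '{stage}' is missing upstream outputs: {missing}")
    return paths


def _stage_simulate(cfg: PipelineConfig, outdir: Path) -> None:
    p = cfg.simulate
    length_aa = int(p.get("length_aa", 200))
    n_mutations = int(p.get("n_mutations", 30))
    sim = SimulationConfig(
        seed=cfg.seed,
        read_error_rate=float(p.get("read_error_rate", 1e-3)),
        mean_mutation_load=float(p.get("mean_mutation_load", 4.4)),
        n_variants=int(p.get("n_variants", 1000)),
        n_reads_naive=int(p.get("n_reads_naive", 5000)),
        n_reads_sorted=int(p.get("n_reads_sorted", 5000)),
        selection_stringency=float(p.get("selection_stringency", 1.0)),
        tsd_length=int(p.get("tsd_length", 8)),
    )
    cds, _ = make_reference(length_aa, cfg.seed)
    design = make_design(cds, n_mutations, cfg.seed)
    io.write_fasta([("reference", cds)], outdir / "reference.fasta")
    design.to_tsv(outdir / "design.tsv")

    genotypes = sample_genotypes(design, sim)
    n_eff = int(p.get("n_effect_mutations", 0))
    eff_rng = _rng(cfg.seed, "effects")
    chosen = sorted(eff_rng.choice(design.ids, size=min(n_eff, len(design)), replace=False))
    effects = {mid: float(p.get("effect_size", 1.0)) for mid in chosen}
    naive, sort = simulate_sort(genotypes, effects, sim)
    naive.write_fastq(outdir / "naive.fastq", design, sim.read_error_rate, cfg.seed)
    sort.write_fastq(outdir / "sorted.fastq", design, sim.read_error_rate, cfg.seed)

    gsim = simulate_genome_and_insertions(
        sim,
        genome_length=int(p.get("genome_length", 400_000)),
        n_contigs=int(p.get("n_contigs", 2)),
        transcript_fraction=float(p.get("transcript_fraction", 0.30)),
        n_insertions=int(p.get("n_insertions", 100)),
        tss_bias=float(p.get("tss_bias", 0.0)),
    )
    io.write_fasta(sorted(gsim.genome.items()), outdir / "genome.fasta")
    gsim.annotation.to_gff3(
        outdir / "annotation.gff3", {c: len(s) for c, s in gsim.genome.items()}
    )
    io.write_fastq(gsim.junction_reads, outdir / "junction_reads.fastq")
    io.write_fasta([("itr_probe", sim.itr_probe)], outdir / "itr_probe.fasta")
    truth = gsim.truth
    truth.genotypes = genotypes
    truth.effects = effects
    truth.to_json(outdir / "ground_truth.json")
    _provenance(outdir, "simulate", p, cfg.seed, [])


def _stage_qc(cfg: PipelineConfig, outdir: Path) -> None:
    ref_p, design_p, naive_p, sorted_p = _require(
        outdir, "qc", "reference.fasta", "design.tsv", "naive.fastq", "sorted.fastq"
    )
    reference = io.read_fasta(ref_p)[0][1]
    design = load_design(design_p, reference)
    q = cfg.qc
    kw = dict(
        min_coverage=float(q.get("min_coverage", 0.95)),
        min_identity=float(q.get("min_identity", 0.85)),
    )
    stats = {}
    for name, reads_path in (("naive", naive_p), ("sorted", sorted_p)):
        result = genotype_reads(io.read_fastq(reads_path), design, **kw)
        result.table.to_csv(
            outdir / f"{name}_genotypes.tsv", sep="\t", index=False, float_format=FLOAT_FORMAT
        )
        result.counts.to_csv(outdir / f"{name}_counts.tsv", sep="\t", index=False)
        variant_abundance(result.genotypes).to_csv(
            outdir / f"{name}_variants.tsv", sep="\t", index=False
        )
        st = library_stats(result.genotypes, total_reads=result.total_reads, counts=result.counts)
        stats[name] = st.to_dict()
    (outdir / "qc_stats.json").write_text(json.dumps(stats, indent=1, sort_keys=True))
    _provenance(outdir, "qc", q, cfg.seed, [ref_p, design_p, naive_p, sorted_p])


def _stage_enrich(cfg: PipelineConfig, outdir: Path) -> None:
    ref_p, design_p, nc_p, sc_p = _require(
        outdir, "enrich", "reference.fasta", "design.tsv", "naive_counts.tsv", "sorted_counts.tsv"
    )
    reference = io.read_fasta(ref_p)[0][1]
    design = load_design(design_p, reference)
    alpha = float(cfg.enrich.get("pseudocount", 0.5))
    table = enrichment_table(
        pd.read_csv(nc_p, sep="\t"), pd.read_csv(sc_p, sep="\t"), design, pseudocount=alpha
    )
    table.to_csv(outdir / "enrichment.tsv", sep="\t", index=False, float_format=FLOAT_FORMAT)
    (outdir / "enrichment_summary.json").write_text(
        json.dumps(enrichment_summary(table), indent=1, sort_keys=True)
    )
    _provenance(outdir, "enrich", {"pseudocount": alpha}, cfg.seed, [ref_p, design_p, nc_p, sc_p])


def _stage_sites(cfg: PipelineConfig, outdir: Path) -> None:
    reads_p, genome_p, gff_p, probe_p = _require(
        outdir, "sites", "junction_reads.fastq", "genome.fasta", "annotation.gff3", "itr_probe.fasta"
    )
    genome = dict(io.read_fasta(genome_p))
    annotation = Annotation.from_gff3(gff_p)
    probe = io.read_fasta(probe_p)[0][1]
    s = cfg.sites
    tsd_length = int(cfg.simulate.get("tsd_length", 8))
    fragments = extract_junctions(
        io.read_fastq(reads_p),
        probe,
        min_itr_match=int(s.get("min_itr_match", 12)),
        min_genomic_len=int(s.get("min_genomic_len", 20)),
    )
    loci = map_fragments(fragments, genome)
    sites = cluster_sites(
        loci, genome, merge_window=int(s.get("merge_window", 5)), tsd_length=tsd_length
    )
    sites_to_bed(sites, outdir / "sites.bed")
    profile = profile_summary(
        sites,
        annotation,
        genome,
        n_random=int(s.get("n_random", 10_000)),
        n_bootstrap=int(s.get("n_bootstrap", 200)),
        seed=cfg.seed,
    )
    profile.to_json(outdir / "profile.json")
    _provenance(outdir, "sites", s, cfg.seed, [reads_p, genome_p, gff_p, probe_p])


_STAGES = {
    "simulate": _stage_simulate,
    "qc": _stage_qc,
    "enrich": _stage_enrich,
    "sites": _stage_sites,
}
STAGE_ORDER = ("simulate", "qc", "enrich", "sites")


def run_pipeline(config: PipelineConfig, stages: tuple[str, ...] = STAGE_ORDER) -> Path:
    """Run the requested stages in dependency order; returns the output
    directory.  Raises :class:`DependencyError` when a stage's upstream
    outputs are missing."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    for stage in STAGE_ORDER:
        if stage not in stages:
            continue
        logger.info("running stage %s", stage)
        _STAGES[stage](config, outdir)
    return outdir
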