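import numpy as np
import pytest

from tnevolve import (
    SimulationConfig,
    make_design,
    make_reference,
    moi_copy_distribution,
    simulate_genome_and_insertions,
    simulate_library,
    simulate_msa,
    simulate_sort,
)
from tnevolve.io import write_fastq
from tnevolve.qc import tally_counts
from tnevolve.simulate import _ztp_rate, variant_sequence


# ------------------------------------------------------------ make_reference


def test_reference_length_arithmetic():
    cds, protein = make_reference(10, seed=1)
    assert len(cds) == 33
    assert len(protein) == 10


def test_reference_deterministic_per_seed():
    assert make_reference(30, seed=5) == make_reference(30, seed=5)
    assert make_reference(30, seed=5) != make_reference(30, seed=6)


def test_reference_translation_against_codon_table(full_reference):
    # independent oracle: translate codon by codon via a literal table lookup
    from Bio.Data.CodonTable import standard_dna_table

    cds, protein = full_reference
    assert len(protein) == 686
    codons = [cds[i : i + 3] for i in range(0, len(cds) - 3, 3)]
    assert "".join(standard_dna_table.forward_table[c] for c in codons) == protein
    assert cds[-3:] in standard_dna_table.stop_codons


def test_reference_too_short_rejected():
    with pytest.raises(ValueError):
        make_reference(9, seed=0)


# --------------------------------------------------------------- make_design


def test_design_positions_distinct_and_nonsynonymous(full_design):
    assert len(full_design) == 108
    positions = [m.aa_pos for m in full_design.mutations]
    assert len(set(positions)) == 108
    assert all(m.wt_aa != m.mut_aa for m in full_design.mutations)


def test_design_empty_and_overfull(small_reference):
    cds, protein = small_reference
    assert len(make_design(cds, 0, seed=1)) == 0
    with pytest.raises(ValueError):
        make_design(cds, len(protein) + 1, seed=1)


# ----------------------------------------------------------- simulate_library


def test_error_free_reads_differ_only_at_designed_codons(small_reference, small_design):
    cds, _ = small_reference
    cfg = SimulationConfig(seed=2, n_variants=5, mean_mutation_load=2.0)
    truth, sample = simulate_library(small_design, cfg, n_reads=20)
    for (_, seq), vi in zip(sample.reads(small_design, error_rate=0.0), sample.variant_indices):
        genotype = truth.genotypes[int(vi)]
        diff_codons = {
            i // 3 + 1 for i in range(len(cds)) if seq[i] != cds[i]
        }
        expected = {small_design.by_id(m).aa_pos for m in genotype}
        assert diff_codons == expected


def test_mutation_load_mean_recovers_configured_value(full_design):
    cfg = SimulationConfig(seed=4, n_variants=10_000, mean_mutation_load=4.4)
    truth, _ = simulate_library(full_design, cfg, n_reads=0)
    loads = np.array([len(g) for g in truth.genotypes])
    se = loads.std(ddof=1) / np.sqrt(len(loads))
    assert abs(loads.mean() - 4.4) < 3 * se


def test_zero_reads_yield_valid_empty_fastq(tmp_path, small_design):
    cfg = SimulationConfig(seed=2, n_variants=5)
    _, sample = simulate_library(small_design, cfg, n_reads=0)
    path = tmp_path / "empty.fastq"
    write_fastq(sample.reads(small_design), path)
    assert path.read_text() == ""


def test_ztp_rate_matches_requested_mean():
    for mean in (1.5, 2.5, 4.4):
        lam = _ztp_rate(mean)
        assert lam / (1 - np.exp(-lam)) == pytest.approx(mean, rel=1e-9)


# -------------------------------------------------------------- simulate_sort


def _per_mutation_freq(sample, design):
    t = tally_counts(sample, design)
    return t["mut"].to_numpy() / (t["mut"] + t["wt"]).to_numpy()


def test_null_selection_leaves_frequencies_unchanged(small_design):
    cfg = SimulationConfig(seed=8, n_variants=200, n_reads_naive=5_000, n_reads_sorted=5_000)
    truth, _ = simulate_library(small_design, cfg, n_reads=0)
    naive, srt = simulate_sort(truth.genotypes, {}, cfg)
    f_n = _per_mutation_freq(naive, small_design)
    f_s = _per_mutation_freq(srt, small_design)
    # binomial sampling error at n = 5000
    se = np.sqrt(f_n * (1 - f_n) / 5_000 + f_s * (1 - f_s) / 5_000)
    assert (np.abs(f_n - f_s) < 4 * se + 1e-12).all()


def test_positive_effect_enriches_in_most_replicates(small_design):
    target = small_design.ids[0]
    wins = 0
    for rep in range(100):
        cfg = SimulationConfig(
            seed=1_000 + rep, n_variants=200, n_reads_naive=2_000, n_reads_sorted=2_000
        )
        truth, _ = simulate_library(small_design, cfg, n_reads=0)
        naive, srt = simulate_sort(truth.genotypes, {target: 2.0}, cfg)
        i = small_design.ids.index(target)
        wins += _per_mutation_freq(srt, small_design)[i] > _per_mutation_freq(naive, small_design)[i]
    assert wins >= 95


def test_zero_stringency_equals_null(small_design):
    cfg = SimulationConfig(
        seed=9, n_variants=100, n_reads_naive=4_000, n_reads_sorted=4_000, selection_stringency=0.0
    )
    truth, _ = simulate_library(small_design, cfg, n_reads=0)
    naive, srt = simulate_sort(truth.genotypes, {m: 5.0 for m in small_design.ids}, cfg)
    f_n = _per_mutation_freq(naive, small_design)
    f_s = _per_mutation_freq(srt, small_design)
    se = np.sqrt(f_n * (1 - f_n) / 4_000 + f_s * (1 - f_s) / 4_000)
    assert (np.abs(f_n - f_s) < 4 * se + 1e-12).all()


def test_empty_genotype_list_rejected(small_design):
    with pytest.raises(ValueError):
        simulate_sort([], {}, SimulationConfig(seed=0))


# ------------------------------------------------------- moi_copy_distribution


@pytest.mark.parametrize(
    "moi,p0,p1,p01",
    [
        (0.0, 1.0, 0.0, 1.0),
        (0.3, 0.7408182206817179, 0.22224546620451535, 0.9630636868862332),
    ],
)
def test_moi_poisson_probabilities(moi, p0, p1, p01):
    d = moi_copy_distribution(moi)
    assert d["0"] == pytest.approx(p0, abs=1e-12)
    assert d["1"] == pytest.approx(p1, abs=1e-12)
    assert d["0"] + d["1"] == pytest.approx(p01, abs=1e-12)


@pytest.mark.parametrize("moi", [0.0, 0.1, 0.3, 1.0, 5.0])
def test_moi_probabilities_normalized(moi):
    assert sum(moi_copy_distribution(moi).values()) == pytest.approx(1.0, abs=1e-12)


def test_negative_moi_rejected():
    with pytest.raises(ValueError):
        moi_copy_distribution(-0.1)


# --------------------------------------- simulate_genome_and_insertions / msa


def test_tsd_flanks_share_duplicated_kmer():
    cfg = SimulationConfig(seed=5, tsd_length=8, read_error_rate=0.0)
    gsim = simulate_genome_and_insertions(
        cfg, genome_length=100_000, n_contigs=1, n_insertions=20
    )
    for s in gsim.truth.insertions:
        g = gsim.genome[s.contig]
        assert len(s.tsd) == 8
        assert g[s.point : s.point + 8] == s.tsd


def test_zero_insertions_give_empty_outputs():
    cfg = SimulationConfig(seed=5)
    gsim = simulate_genome_and_insertions(
        cfg, genome_length=50_000, n_contigs=1, n_insertions=0
    )
    assert gsim.truth.insertions == []
    assert gsim.junction_reads == []


def test_generators_are_deterministic_per_seed(tmp_path, small_design):
    cfg = SimulationConfig(seed=42, n_variants=20, read_error_rate=0.01)
    files = []
    for tag in ("a", "b"):
        _, sample = simulate_library(small_design, cfg, n_reads=50)
        p = tmp_path / f"{tag}.fastq"
        sample.write_fastq(p, small_design, error_rate=0.01, seed=42)
        files.append(p.read_bytes())
    assert files[0] == files[1]
    g1 = simulate_genome_and_insertions(cfg, genome_length=60_000, n_contigs=1, n_insertions=10)
    g2 = simulate_genome_and_insertions(cfg, genome_length=60_000, n_contigs=1, n_insertions=10)
    assert g1.genome == g2.genome and g1.junction_reads == g2.junction_reads


def test_msa_determinism_and_planting():
    r1, p1 = simulate_msa(8, 3, 0.9, seed=11)
    r2, p2 = simulate_msa(8, 3, 0.9, seed=11)
    assert r1 == r2 and p1 == p2
    # planted columns really are conserved at >= the requested level
    rows = dict(r1)
    target = rows.pop("target")
    for cand in p1:
        col = cand.position - 1
        agree = sum(1 for seq in rows.values() if seq[col] == cand.consensus_aa)
        assert agree / len(rows) >= 0.9
        assert target[col] == cand.target_aa != cand.consensus_aa


def test_msa_argument_validation():
    with pytest.raises(ValueError):
        simulate_msa(1, 0, 0.9, seed=0)
    with pytest.raises(ValueError):
        simulate_msa(5, 200, 0.9, seed=0, n_columns=100)
    with pytest.raises(ValueError):
        simulate_msa(5, 2, 1.5, seed=0)
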