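import numpy as np
import pandas as pd
import pytest

from tnevolve import (
    Annotation,
    InsertionSite,
    SimulationConfig,
    Transcript,
    classify_context,
    cluster_sites,
    distance_to_tss,
    extract_junctions,
    map_fragments,
    profile_summary,
    simulate_genome_and_insertions,
)
from tnevolve._seq import revcomp
from tnevolve.integration import load_loci

PROBE = "CAGTGACGAAAATCTTGTTCACAGTGACGT"


def _toy_genome(seed=0, length=5_000):
    rng = np.random.default_rng(seed)
    return {"chr1": "".join(rng.choice(list("ACGT"), size=length))}


# ---------------------------------------------------------- junction trimming


def test_probe_plus_genomic_is_trimmed():
    genomic = "ACGT" * 10
    frags = extract_junctions([("r1", PROBE + genomic)], PROBE)
    assert frags == [("r1", genomic)]


def test_pure_transposon_read_discarded():
    frags = extract_junctions([("r1", PROBE), ("r2", PROBE + PROBE[:10])], PROBE)
    assert frags == []


def test_short_genomic_fragment_discarded():
    frags = extract_junctions([("r1", PROBE + "ACGTACGTAC")], PROBE, min_genomic_len=20)
    assert frags == []


def test_reverse_orientation_junction_recognized():
    genomic = "TTACGGATCCAGGAAACCTTGGAATT"
    frags = extract_junctions([("r1", revcomp(PROBE + genomic))], PROBE)
    assert frags == [("r1", genomic)]


def test_truncated_probe_terminus_matches():
    genomic = "TTACGGATCCAGGAAACCTTGGAATT"
    frags = extract_junctions([("r1", PROBE[-15:] + genomic)], PROBE, min_itr_match=12)
    assert frags == [("r1", genomic)]
    assert extract_junctions([("r1", PROBE[-8:] + genomic)], PROBE, min_itr_match=12) == []


def test_empty_probe_rejected():
    with pytest.raises(ValueError):
        extract_junctions([], "")


# ----------------------------------------------------------------- mapping


def test_exact_fragment_maps_to_origin():
    genome = _toy_genome()
    frag = genome["chr1"][1000:1040]
    loci = map_fragments([("f", frag)], genome)
    row = loci.iloc[0]
    assert (row["contig"], row["position"], row["strand"], row["status"]) == (
        "chr1",
        1000,
        "+",
        "mapped",
    )


def test_duplicated_fragment_flagged_multimap():
    genome = {"chr1": "A" * 50 + "CCGGTTAACCGGTTAACCGGAAAA" + "T" * 50 + "CCGGTTAACCGGTTAACCGG" + "G" * 30}
    loci = map_fragments([("f", "CCGGTTAACCGGTTAACCGG")], genome)
    assert loci.iloc[0]["status"] == "multimap"


def test_unmapped_fragment_flagged():
    genome = _toy_genome()
    loci = map_fragments([("f", "X" * 0 + "GGGGGGGGGGGGGGGGGGGGGGGGGGGGGGGG")], genome)
    assert loci.iloc[0]["status"] in ("unmapped", "multimap")


def test_strand_symmetry_of_junction_coordinates():
    """A fragment and its reverse complement report the same between-base
    junction interval from opposite sides."""
    genome = _toy_genome(3)
    frag = genome["chr1"][2000:2040]
    plus = map_fragments([("f", frag)], genome).iloc[0]
    minus = map_fragments([("f", revcomp(frag))], genome).iloc[0]
    assert plus["strand"] == "+" and minus["strand"] == "-"
    assert plus["position"] == 2000
    assert minus["position"] == 2040


def test_load_external_loci_converts_coordinates(tmp_path):
    p = tmp_path / "loci.tsv"
    pd.DataFrame(
        {"contig": ["chr1"], "position": [1001], "strand": ["+"], "fragment_id": ["f"]}
    ).to_csv(p, sep="\t", index=False)
    loci = load_loci(p)
    assert loci.iloc[0]["position"] == 1000
    assert loci.iloc[0]["status"] == "mapped"


# ---------------------------------------------------------------- clustering


def _loci_frame(rows):
    return pd.DataFrame(
        rows, columns=["fragment_id", "contig", "position", "strand", "status"]
    )


def test_identical_loci_merge_with_summed_support():
    genome = _toy_genome()
    loci = _loci_frame([("a", "chr1", 100, "+", "mapped"), ("b", "chr1", 100, "+", "mapped")])
    sites = cluster_sites(loci, genome, tsd_length=8)
    assert len(sites) == 1
    assert sites[0].support == 2


def test_opposite_junctions_offset_by_tsd_collapse():
    genome = _toy_genome(1)
    p = 700
    loci = _loci_frame(
        [("a", "chr1", p, "+", "mapped"), ("b", "chr1", p + 8, "-", "mapped")]
    )
    sites = cluster_sites(loci, genome, tsd_length=8)
    assert len(sites) == 1
    s = sites[0]
    assert s.point == p and s.support == 2
    assert s.tsd == genome["chr1"][p : p + 8]


def test_distant_loci_stay_separate():
    genome = {"chr1": "ACGT" * 5000}
    loci = _loci_frame(
        [("a", "chr1", 100, "+", "mapped"), ("b", "chr1", 10_100, "+", "mapped")]
    )
    assert len(cluster_sites(loci, genome)) == 2


def test_minus_only_cluster_back_computes_insertion_point():
    genome = _toy_genome(2)
    loci = _loci_frame([("a", "chr1", 508, "-", "mapped")])
    sites = cluster_sites(loci, genome, tsd_length=8)
    assert sites[0].point == 500


# ------------------------------------------------------ distances and context


def _annotation():
    # chr1: transcript 1000-2000 (+, TSS 1000) with CDS exon 1200-1400,
    #       transcript 5000-6000 (-, TSS 5999)
    return Annotation(
        [
            Transcript("t1", "chr1", 1000, 2000, "+", [(1000, 1500), (1700, 2000)], [(1200, 1400)]),
            Transcript("t2", "chr1", 5000, 6000, "-", [(5000, 6000)], []),
        ]
    )


def _site(point, contig="chr1"):
    return InsertionSite(contig=contig, point=point, strand="+", tsd="ACGTACGT", support=1)


def test_site_at_tss_has_zero_distance():
    d = distance_to_tss([_site(1000)], _annotation())
    assert d.iloc[0]["tss_distance"] == 0


def test_distance_to_single_tss():
    d = distance_to_tss([_site(1500)], _annotation())
    assert d.iloc[0]["tss_distance"] == 500


def test_nearest_tss_wins():
    # distances 3700 to TSS@1000 and 1299 to TSS@5999
    d = distance_to_tss([_site(4700)], _annotation())
    assert d.iloc[0]["tss_distance"] == 1299


def test_minus_strand_tss_is_three_prime_end_of_span():
    ann = _annotation()
    assert 5999 in ann.tss_positions("chr1")


def test_unannotated_contig_flagged():
    d = distance_to_tss([_site(10, contig="chrUn")], _annotation())
    assert not d.iloc[0]["annotated"]


def test_context_precedence():
    ann = _annotation()
    assert classify_context(_site(1300), ann) == "coding_exon"
    assert classify_context(_site(1600), ann) == "transcript_noncoding"  # intron
    assert classify_context(_site(1100), ann) == "transcript_noncoding"  # UTR exon
    assert classify_context(_site(3000), ann) == "outside_transcript"
    assert classify_context(_site(5500), ann) == "transcript_noncoding"


def test_distance_invariant_to_record_order():
    ann_fwd = _annotation()
    ann_rev = Annotation(list(reversed(ann_fwd.transcripts)))
    pts = [_site(p) for p in (0, 999, 1000, 2500, 5999)]
    d1 = distance_to_tss(pts, ann_fwd)["tss_distance"].tolist()
    d2 = distance_to_tss(pts, ann_rev)["tss_distance"].tolist()
    assert d1 == d2


# ------------------------------------------------------------------- profiles


def test_all_sites_at_tss_give_zero_median():
    ann = _annotation()
    genome = {"chr1": "A" * 10_000}
    sites = [_site(1000), _site(5999)]
    prof = profile_summary(sites, ann, genome, n_random=100, n_bootstrap=20, seed=0)
    assert prof.median_tss_distance == 0.0


def test_zero_bootstrap_reports_absent_se():
    ann = _annotation()
    genome = {"chr1": "A" * 10_000}
    prof = profile_summary([_site(1234)], ann, genome, n_random=50, n_bootstrap=0, seed=0)
    assert prof.median_tss_distance_se is None
    assert prof.median_tss_distance == pytest.approx(234.0)


def test_empty_site_list_rejected():
    with pytest.raises(ValueError):
        profile_summary([], _annotation(), {"chr1": "A" * 100})


def test_class_fractions_sum_to_one():
    ann = _annotation()
    genome = {"chr1": "G" * 10_000}
    prof = profile_summary(
        [_site(p) for p in (10, 1300, 1600, 4000)], ann, genome, n_random=500, seed=3
    )
    assert sum(prof.class_fractions.values()) == pytest.approx(1.0, abs=1e-9)
    assert sum(prof.baseline_class_fractions.values()) == pytest.approx(1.0, abs=1e-9)


def test_uniform_baseline_matches_annotated_transcript_fraction():
    cfg = SimulationConfig(seed=6, read_error_rate=0.0)
    gsim = simulate_genome_and_insertions(
        cfg, genome_length=400_000, n_contigs=1, n_insertions=30
    )
    ann = gsim.annotation
    genome = gsim.genome
    rng = np.random.default_rng(0)
    n = 10_000
    in_tx = sum(
        ann.context("chr1", int(rng.integers(0, len(genome["chr1"])))) != "outside_transcript"
        for _ in range(n)
    ) / n
    frac = ann.transcript_bp() / len(genome["chr1"])
    assert abs(in_tx - frac) < 3 * np.sqrt(frac * (1 - frac) / n)


# ----------------------------------------------------------- GFF3 round trip


def test_gff3_round_trip(tmp_path):
    ann = _annotation()
    p = tmp_path / "ann.gff3"
    ann.to_gff3(p, {"chr1": 10_000})
    back = Annotation.from_gff3(p)
    assert len(back.transcripts) == 2
    t1 = next(t for t in back.transcripts if t.start == 1000)
    assert t1.exons == [(1000, 1500), (1700, 2000)]
    assert t1.cds == [(1200, 1400)]
    assert sorted(back.tss_positions("chr1").tolist()) == [1000, 5999]


def test_transcript_bp_merges_overlaps():
    ann = Annotation(
        [
            Transcript("a", "c", 0, 100, "+", [(0, 100)], []),
            Transcript("b", "c", 50, 150, "+", [(50, 150)], []),
        ]
    )
    assert ann.transcript_bp() == 150
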