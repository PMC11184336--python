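# Methods

This note documents the models, numerical choices and limitations behind
`tnevolve`.  Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Candidate substitutions from conservation

A column of a protein family alignment yields a candidate substitution when
the modal residue among the *non-target* rows reaches frequency
`min_conservation` (default 0.6) with non-gap coverage `min_coverage`
(default 0.5), and the target sequence carries a different residue there.
The consensus deliberately excludes the target row: the question asked is
"what does the rest of the family keep that this enzyme lost", and including
the target would dilute exactly the signal being sought.  Gaps and ambiguous
residues (X, B, Z) are excluded from frequency denominators; positions are
reported in target-sequence numbering with target gaps skipped, labelled
`<wt><pos><consensus>` (e.g. `V356L`).  No thresholds are canonical for this
procedure — historically the step involved manual curation — so both are
exposed as flags, and raising `min_conservation` provably never adds
candidates (a tested monotonicity property).

Phylogenetic weighting and structure-guided filtering are out of scope: the
procedure class implemented here is frequency-based column consensus.

## Library simulation and the selection model

The generator's defaults describe the screening regime the pipeline
targets:

| parameter | default | meaning |
|---|---|---|
| `mean_mutation_load` | 4.4 | mean designed substitutions per variant cDNA |
| `n_variants` | 10,000 | unique library members |
| `n_reads_naive/sorted` | 200,000 | reads per sequenced population |
| `read_error_rate` | 1e-3 | per-base substitution rate (CCS-grade) |
| `selection_stringency` | 1.0 | exponent scale of the selection weight |
| `tsd_length` | 8 | target-site duplication length (hAT family) |

**Mutation load.** Only mean loads are ever reported for such libraries, not
a distribution; the generator uses a zero-truncated Poisson whose rate is
solved (Brent) so that the *truncated* mean equals `mean_mutation_load`.
This is a stand-in choice, not an empirical claim; a variant with zero
designed mutations is wild type and not a library member, hence the
truncation.  Loads are capped at the catalogue size.

**Selection.** Each mutation may carry an activity effect, additive on a log
scale; a variant's probability of surviving selection and sorting is taken
proportional to `exp(stringency × Σ effects)`.  The exponential form is a
modeling choice motivated by selection on multi-copy transposition events
(survival through k independent integration hurdles compounds
multiplicatively); it is not a claim about any particular enzyme.  Naive
reads sample variants uniformly; sorted reads sample with these weights.
Epistasis is deliberately absent, which is what makes per-mutation
parameter recovery well-posed in the closed-loop tests.

**Sequencing error.** Substitutions only, i.i.d. at `read_error_rate`;
indels are off by default (`indel_rate`), reflecting circular-consensus
long reads.  Real CCS data additionally shows homopolymer-biased indels and
chimeric molecules from library construction; passing tests on this
generator therefore demonstrates correctness of the counting and scoring
machinery, not robustness to every long-read artifact.

**Seeding.** One master seed; every sub-generator derives an independent
stream as `default_rng([seed, crc32(label)])`, so adding a generator never
perturbs existing outputs.  Identical seeds give byte-identical files.

## Read genotyping

Reads are filtered to full-length CDS alignments (edlib, infix mode;
reverse complement auto-detected): aligned reference coverage ≥ 0.95 and
identity ≥ 0.85 by default.  The thresholds are not canonical and are
CLI-exposed; pass rate is monotone in both (tested).

Coordinates for codon scanning come from a *global* (end-pinned) alignment
of the accepted read.  Two numerical quirks of unit-cost edit alignment are
handled explicitly:

* an infix alignment may clip a reference end to dodge an edge mismatch,
  shifting the frame of edge codons — hence the end-pinned pass;
* a codon substitution (up to 3 mismatches) ties in edit distance with a
  cancelling insertion/deletion pair, and the aligner may emit either.
  Codons are therefore read off the *diagonal voted by flanking anchors*
  (±15 bases): if the flanks agree on a diagonal, the codon bases are taken
  from it, which is exactly what a substitution-preferring affine-gap
  aligner would report.  A genuine indel shifts the diagonal, leaves no
  shared vote, and the position is classified OTHER.

Each designed position is then codon-exact: reference codon → WT, designed
replacement codon → MUT, anything else → OTHER.  OTHER positions count
toward neither tally, so sequencing errors cannot inflate either count; the
per-position misclassification rate at error rate e is the chance of an
error inside the codon, `1-(1-e)^3 ≈ 3e`, and the suite verifies that the
pipeline adds nothing on top of it (pipeline counts equal a direct per-read
codon re-scan).  A variant's genotype is the exact set of MUT ids; OTHER
positions do not distinguish variants.  Mean mutation load is averaged over
unique variants, not reads.

For large simulated screens the per-mutation counts are tallied at the
genotype-ledger level (each sampled read contributes its variant's true
genotype), which is equivalent to scanning error-free reads; the
equivalence to the sequence-level path is itself a tested invariant, and
the sequence path is used wherever reads are materialized.

`combinatorial_space(n, k) = Σ_{j=1..k} C(n, j)` in exact integer
arithmetic gives the design space: 5,569,137 variants for 108 mutations up
to load 4, and `2^108 − 1 ≈ 3.2×10^32` over all loads.  (A published figure
of 7,558 double mutants for a 108-mutation catalogue does not match
`C(108,2) = 5,778`; the discrepancy is unexplained and the exact value is
reported rather than matched.)

## Enrichment statistics

For designed mutation m with mutant/wild-type counts in each population:

    F   = (Reads_mut + α) / (Reads_mut + Reads_wt + 2α)
    E   = F_sort / F_naive
    WES = ln(E) × sqrt(Reads_mut,sort + Reads_mut,naive)

With pseudocount α = 0 these are the literal screen formulas and error on
zero counts; the default α = 0.5 (Jeffreys-style) is applied inside F only
— the weight term always uses raw mutant counts, preserving the printed
WES form.  Whether the original analysis floored zero counts is unknown,
so both modes exist and rows whose score is undefined at α = 0 are flagged,
never dropped.  Ranking is by WES descending with ties broken by mutation
id.  Counts are reported per amino-acid substitution; detection is
codon-exact upstream.

A note on evaluation: with a truth vector of 10 active mutations (+1) among
108, tie-corrected Spearman correlation between truth and *any* ranking is
bounded at 0.502 (98 tied zeros); the screen reaches that bound and places
all ten true positives in the WES top 20 across seeds, which is the more
informative recovery metric.

## Integration-site profiling

Junction reads are trimmed by matching at least `min_itr_match` (default
12) terminal bases of the ITR probe as a read prefix in either orientation;
matching is exact, which suffices at the simulated error rate because every
junction is covered by multiple reads and mismatched copies simply drop
out.  Remainders shorter than `min_genomic_len` (default 20) — including
transposon-internal reads — are discarded.

Fragments are placed by exact search over both strands of the genome
(linear scan; adequate and auditable at desk scale — a seeded external
mapper can be substituted via the `load_loci` import path, and bit-exact
replication of any external toolchain is explicitly not attempted).
Fragments with multiple placements are flagged `multimap`, with none
`unmapped`; both are excluded from site calling.

Deduplication (no canonical rule exists, so this one is the package's own):
same-strand junction coordinates within `merge_window` (default 5) merge,
support summed, cluster position = support-weighted mode (leftmost on
ties); a plus cluster at p and minus cluster at p + `tsd_length` (within
the merge window) collapse into one insertion at p, its TSD read off the
genome — which is why recovered TSDs are exact whenever the point is.
Unpaired minus-side clusters back-compute the point as q − `tsd_length`.

Distances are unsigned, to the nearest TSS of any transcript (strand-aware
5′ end); context classes use precedence coding_exon > transcript_noncoding
> outside_transcript.  The profile compares observed class fractions to a
uniform-random baseline of `n_random` (default 10,000) positions and
reports observed/baseline ratios.  The median TSS distance carries a
bootstrap standard error over site resamples (`n_bootstrap` = 200 default);
reporting an SE is a labelled convention choice, since published "±" values
on such medians rarely state their definition.  Coordinates are 0-based
half-open internally; GFF3 is 1-based per the standard, BED 0-based.

The synthetic genome (default 2 Mb across 2 contigs for the closed-loop
checks; 400 kb in the bundled pipeline config) tiles genes so transcripts
cover ≈30% of the genome with ≈65% exonic bases of which the central 80%
is CDS.  It has uniform base composition and no repeats, so multimapping is
rare by construction; real genomes would demand a real aligner and
repeat-aware site filtering.

## Pipeline

Stages simulate → qc → enrich and simulate → sites run under one YAML
config with a master seed; unknown keys are rejected.  Every stage writes a
provenance JSON (parameters, seed, SHA-256 of inputs) sufficient to re-run
it in isolation.  Floats are serialized at 6 significant digits and counts
as integers, keeping reruns byte-identical (a tested property).  ddPCR copy
number is the final-formula helper `2 × target / reference`, the factor 2
being the diploid copies of the reference locus.

## Problem sizes

The default test and acceptance runs use: 10 seeds × 200,000 reads per
population for screen recovery; 50 replicates × 20,000 reads for null
calibration; 600 genotyped long reads for QC accuracy; a 2-Mb genome with
500 insertions for the integration loop.  These sizes were chosen so every
statistical check has comfortable power while the whole suite stays quick
on a single CPU.

## Known limitations

* No epistasis and no variant-level enrichment score; combining top
  mutations into a final enzyme remains a manual step.
* No PCR/shuffling chemistry, lentiviral sequence bias, or capture
  efficiency in the generator; MOI-based copy-number modeling is provided
  only as the Poisson helper.
* The exact-match junction extractor and mapper are desk-scale tools, not
  replacements for production aligners on real genomes.
* The candidate finder reproduces a procedure class; any historically used
  catalogue of designed mutations is not recoverable from thresholds alone.
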