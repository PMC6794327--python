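# Methods

This note documents the models, conventions and numerical choices behind
`genostream`, in the spirit of the methods documentation shipped by
simulation and statistics packages.

## Data model and coordinates

All intervals are 0-based half-open on the forward strand; GFF3 (1-based
inclusive) and GenBank conversions happen only at the I/O boundary. A
feature spanning the origin of a circular replicon is stored as two parts
sharing one `logical_id`; spacer, overlap and length computations treat the
parts as one feature. Nucleotide ambiguity codes other than N are normalised
to N with a logged count; translations use the bacterial genetic code
(table 11), prefer annotated translations when present, and exclude CDS
whose translation contains an internal stop (with a warning).

## Streamlining indicators

* **GC%** is computed over unambiguous nucleotides only (N excluded from
  numerator and denominator).
* **Intergenic spacers** are strand-agnostic gaps between consecutive
  annotated gene features (CDS + rRNA + tRNA) per replicon; overlapping
  neighbours contribute a spacer of 0 rather than a negative value, and
  circular replicons include the wrap-around gap. Rationale: spacer length
  is a non-negative quantity and the overlap case is reported separately.
* **Coding density** is the interval *union* of CDS divided by genome size,
  so heavy overlap can never push it above 100%.
* **Overlapping CDS%** counts CDS sharing ≥1 bp with any other CDS,
  strand-agnostic.
* **Stop-codon usage** tallies the terminal codon of each CDS on its coding
  strand; only canonical TAA/TAG/TGA enter the percentages and
  non-canonical cases are counted separately. TGA is reported alongside
  TAA/TAG so the three fractions verifiably sum to 100.
* **Atom composition** uses residue formulas (free amino acid minus one
  water, e.g. Gly C2H3NO, Lys C6H12N2O, Arg C6H12N4O, Cys C3H5NOS). Both
  mean atoms per residue and element mol% (share of all C+H+N+O+S atoms)
  are reported because "atoms per amino acid (mol%)" is ambiguous; the
  tests and figures treat atoms-per-residue as primary.
* **Regulator counts** (histidine kinases, sigma factors) match product
  annotations against configurable case-insensitive pattern sets; whether a
  published count came from product text or COG categories is generally
  unknowable from the outside, hence the patterns are user-replaceable.

## Alignment engine

Protein alignment is Smith–Waterman with affine gaps under BLOSUM62 with
BLAST-convention penalties (a gap of length *g* costs 11 + *g*); nucleotide
scoring is +2/−3 with gaps costing 5 + 2*g*. Identity is identities per
alignment column, similarity the fraction of columns with a positive
substitution score, and coverage the aligned span over the full sequence
length (the conservative min of query/subject coverage is thresholded
wherever a published cutoff says "coverage" unqualified). E-values follow
Karlin–Altschul with the standard gapped constants (λ=0.267, K=0.041 for
BLOSUM62 11/1; λ=0.625, K=0.41 for +2/−3) and the summed subject length as
search space. Exact replication of BLAST e-values is not promised — the
thresholds are the contract — and batch search prunes pairs whose *exact*
optimal score already falls below the score needed to reach the e-value
gate, so no passing hit is lost.

The suite verifies the engine against a brute-force affine DP oracle on
random short pairs (exact score agreement), plus symmetry and monotonicity
properties.

### Genome-scale nucleotide fast path

Aligning kilobase fragments or millions of reads against whole replicons by
full dynamic programming is quadratic and not desk-scale. ANI fragments and
metagenomic reads are therefore placed by exact k-mer seeding (k=16 for
fragments, k=13 for reads, both strands, diagonal voting) and aligned
within a small window by banded edit-distance alignment (edlib), with
matches/mismatches/gaps taken per column from the extended CIGAR. Because
the windowed alignment is glocal (the whole query must align), each
alignment is trimmed to its maximum-scoring contiguous run of columns
(+2 match / −3 mismatch / −4 gap column), restoring local-alignment
semantics: chance matches collapse to short segments that fail the
alignable-length rule instead of spanning the fragment at ~50% identity.
Queries with no seed on either strand are treated as non-alignable, which
is the behaviour of any seeded search tool.

## Orthology, paralogy, pan-genome

Ortholog families are connected components (single linkage) of the graph
whose edges are reciprocal hits between genomes passing ≥50% identity and
≥50% min-coverage. Because the scoring scheme is symmetric and coverage is
the pair minimum, one search direction determines reciprocity. Single
linkage is the simplest faithful reading of an all-vs-all protocol with
fixed cutoffs; it is stated here so results are interpretable. Every
protein belongs to exactly one family (singletons included), so family
sizes partition the proteome. The accumulation curve averages 100 seeded
random genome orderings.

Paralogs are proteins with ≥1 non-self within-genome hit at ≥80% coverage,
≥70% similarity (positive-scoring columns, the BLAST "positives" reading)
and ≥50% identity. Self-hits are excluded by protein id, not sequence, so
identical twin genes count. The single-copy core (families with exactly one
member in every genome) is exported one FASTA per family with records
ordered by genome, ready for alignment and concatenation; tree inference
itself is out of scope.

## ANI / AAI and rank calls

ANI cuts the query genome into consecutive 1,020-bp fragments and keeps a
fragment when its (trimmed) alignment to the subject genome reaches ≥30%
identity over ≥70% of the fragment; ANI is the mean identity of kept
fragments and the published value is the symmetric mean of both directions.
All four constants are configurable and logged. AAI averages identity over
reciprocal best-hit protein pairs kept at ≥30% identity and ≥70% coverage.
Rank calls: same species at ANI ≥95 or AAI ≥95; different genus below the
65% AAI hard cutoff; same genus at ≥70%; the 65–70% band is reported as
`ambiguous` rather than forced to a single verdict.

## Recruitment and RPKG

A read is recruited when its best alignment has length ≥50 bp, identity
≥95% (both evaluated over the aligned region — the most literal reading of
the cutoffs) and e-value ≤1e−5; each read counts at most once per genome
and recruitment is per genome, not competitive across genomes. Genomes must
have their annotated rRNA loci masked first (`mask_rrna`; an explicit
waiver is available), and hits overlapping masked blocks by more than half
the alignment are discarded. RPKG = reads / (genome kb × metagenome Gb),
with metagenome size taken as the summed read length of the input file.
Where a read has several local hits it is still counted once (reads, not
HSPs).

## Module profiles

Within each metabolic module, reference proteins are clustered greedily
longest-first at ≥90% identity over ≥90% of the shorter sequence (the
classic greedy-clustering convention; word-filter heuristics of specific
tools are not reproduced). Cluster members are aligned by center-star
progressive alignment (center = member with the highest summed pairwise
score; terminal gaps free), weighted with Henikoff position-based weights,
and converted to per-column log-odds in bits against Robinson–Robinson
background frequencies with a background-proportional pseudocount (τ=1);
all-gap columns are dropped with a warning. Scanning is local affine DP of
a sequence against the profile (gap open 4 bits, extend 0.5 bits — members
of one functional family rarely need gaps, so the penalties mainly guard
against spurious gapped chaining). E-values multiply the tail of a Gumbel
distribution fitted to scores of composition-preserving shuffled decoys
(default 500) by the number of sequences scanned; a module is present in a
genome when ≥1 of its profiles (configurable) hits ≥1 protein at e ≤1e−3.
This is a deliberately transparent profile model, not a full
insert/delete-state HMM; an external profile-search backend can substitute
where bit-for-bit parity with HMM tooling is required.

## Statistics

Each indicator is tested against genome size (Mbp) or GC (%) with Pearson r
(two-sided t-test on n−2 df, the primary significance call), Spearman rho
(tie-aware) and an OLS fit. Zero variance in either variable yields a
flagged undefined result instead of NaN propagation. No multiple-testing
correction is applied per panel — matching per-panel testing practice — but
a Holm-adjusted column is emitted for transparency. The suite checks type-I
calibration on null cohorts (rejection rate 0.05 ± 0.02 at α=0.05 over
1,000 replicates).

## Synthetic data

Every generator is a pure function of (spec, seed) and emits a truth record
with the realised value of each quantity later estimated.

* **Genomes.** Genes and geometric spacers are laid out around a circle
  until the target size is reached; the closing spacer absorbs the
  remainder. CDS lengths are lognormal (default: exp(µ)=854 bp, σ=0.35 —
  typical bacterial gene lengths); default size 1.3 Mbp, GC 36%, spacer
  mean 60 bp and stop bias (0.8, 0.1, 0.1) emulate a streamlined pelagic
  methylotroph. Codon choice reconciles the GC target with the amino-acid
  bias through a single exponential tilt on synonymous codons,
  `w(codon) ∝ exp(t·GC(codon))`, with `t` solved by root-finding so the
  expected coding GC (start/stop included) equals the target; spacers are
  drawn at the same GC, so the expected genomic GC equals the target
  regardless of coding density. Unreachable combinations raise a
  feasibility error with the achievable GC range. Gene overlaps are planted
  as the 1-bp stop/start sharing motif between co-oriented minus-strand
  neighbours, which keeps every translation and terminal stop exactly
  consistent with the genome sequence (overlapping genes draw their stop
  from {TAA, TGA}, a small documented distortion of the stop bias at the
  default 5% overlap rate). Paralog families, regulator products and rRNA
  loci are planted with exact bookkeeping. Realised tolerances asserted in
  the suite: GC within ±0.5 points at ≥1 Mbp, mean CDS within 5% of the
  lognormal mean, spacer mean within 10%, stop fractions within a binomial
  99% CI.
* **Divergence.** `evolve_genome` places substitutions uniformly
  (selection-agnostic — sufficient for ANI/AAI/orthology recovery, and a
  stated limitation: no dN/dS structure, no small indels), removes lost
  genes with their intervals closed (overlapping genes are never chosen, so
  survivors keep exact frames) and inserts freshly drawn genes into
  intergenic positions. `evolve_proteome` mutates residues to a *different*
  amino acid, so a divergence of d yields an expected identity of exactly
  1−d; within-family pairwise identity targets are inverted analytically
  from the two-sided mutation model including replacement collisions.
* **Metagenomes.** Reads sample genomes position-uniformly on either strand
  with iid substitution errors (default 100 bp, 1% error); the remaining
  abundance is random background at 50% GC. No realistic sequencer error
  profile is modelled.
* **Profile-level cohorts** for the statistics layer draw indicator values
  from linear responses to genome size or GC with Gaussian noise — they
  exercise the inference machinery at scale without the cost of generating
  full genome cohorts, and make no claim about mechanistic coupling between
  indicators.

What passing recovery tests on these generators shows is that the pipeline
measures what it claims on data matching its assumptions (uniform
substitution, iid errors, annotation consistent with sequence); real
genomes add misannotation, repeats, mobile elements, compositional
heterogeneity and rearrangements that the generators deliberately omit.

## Problem sizes and determinism

The shipped tests and the acceptance script run the generators at 40 kb –
1 Mb genome sizes, 10⁴-read metagenomes, 80-family pangenomes and
1,000-replicate null calibrations — sizes chosen so each stage's sampling
error is far below its assertion tolerance while the whole suite stays
interactive. All randomness flows through explicit integer seeds; identical
(spec, seed) inputs give byte-identical FASTA/GFF3/FASTQ outputs, and the
pipeline manifest records versions, seeds, thresholds and input/output
checksums so a run can be reproduced exactly.

## Known limitations

* The internal search is exhaustive (no k-mer heuristics for proteins), so
  all-vs-all proteome comparisons beyond a few hundred proteins per genome
  benefit from the pluggable external search backend.
* Fragment/read placement requires an exact seed; divergence beyond ~15%
  nucleotide identity loss degrades seeding before alignment does.
* The profile scanner has no insert/delete states and its e-values are
  calibrated per profile by decoy fitting, not by conjugate-gradient
  parameter estimation; ranking, not absolute parity with HMM packages, is
  the design goal.
* ANI/AAI/rank cutoffs are bulk-genome heuristics; the `ambiguous` band is
  reported deliberately instead of a hard genus verdict.
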