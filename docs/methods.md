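# Methods

This note documents the models and procedures `mitobench` implements, the
parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic benchmark does and does not show
about real data.

## Problem setting

A circular mitochondrial chromosome assembled from nanopore long reads is
compared against a trusted ("gold standard") reference assembly of the
same locus, typically built from short reads. At ~99.9 % identity the
interesting signal is not bulk identity but the *structure* of the few
dozen residual discordances: nanopore basecalling characteristically
miscounts homopolymer run lengths, so errors concentrate as short indels
at the flanks of identical-base runs, and a single frameshifting indel
inside a protein-coding gene (PCG) surfaces as internal stop codons that
break annotation.

## Circular normalization

Assemblers report a circular contig at an arbitrary strand and rotational
phase, so both must be normalized before a linear alignment is
meaningful.

* **Strand.** Both strands of the assembly are reduced to circular k-mer
  multisets (default word size k = 15) and the strand sharing more
  k-mers with the reference's multiset wins. An exact tie is an error
  signal, not a silent choice; the caller may retry with smaller k. At
  k = 15 a random 16.7 kb genome shares essentially no k-mers with its
  reverse complement, so the margin is enormous for real inputs.
* **Rotation.** The reference's leading `anchor_len` bases (default 31)
  are scanned against the doubled assembly string; the rotation placing
  the best exact-match locus at position 0 wins, ties breaking toward the
  smallest offset. This is O(n · anchor_len) and exact for assemblies
  within the identity range this tool targets; if fewer than half the
  anchor bases match anywhere, the assembly is rejected as a likely
  failed assembly or wrong organism. A full circular alignment would be
  quadratically more expensive and is unnecessary at ≥ 99 % identity.
  Linear-topology inputs pass through unrotated with a warning.

## Alignment

Exactly two sequences are compared per benchmark, so the pipeline uses an
optimal pairwise global (end-to-end) alignment rather than a
multiple-alignment heuristic: it is deterministic, and its optimality is
testable against brute-force dynamic programming on small instances. The
implementation is the three-state Gotoh algorithm (numba-compiled, full
traceback), with a gap of length L costing `gap_open + (L−1)·gap_extend`.

Default scoring: match +2, mismatch −3, gap open −5, gap extend −2. The
penalties are chosen so that contiguous indels are preferred over
scattered mismatches (one 2 bp gap at −7 beats two mismatches at −6 only
when no base matches; a clean indel always beats re-pairing a homopolymer
miscount as substitutions), matching the indel-dominated error structure
of nanopore consensus sequence. All four values are configurable.
Terminal gaps are scored like internal ones: after rotation there is no
privileged end on a circle. A guard refuses DP instances above 10⁹ cells
(mitogenome pairs are ~2.8 × 10⁸).

**Canonical gap placement.** The position of an indel inside a
homopolymer run is alignment-arbitrary. Every gap run is therefore
shifted to its leftmost content-preserving placement before
classification: a run slides one column left whenever the preceding
column is aligned and the base-carrying row holds the same character at
the column entering and the column leaving the run (neither ungapped
sequence nor any column's match status changes). The procedure is
idempotent, and the test suite verifies that the whole slide-equivalence
class of an alignment collapses to one canonical form with one error
profile.

## Error taxonomy

Carriers are extracted from the canonical alignment: one insertion per
maximal gap run in the reference row, one deletion per maximal run in the
assembly row, one substitution per mismatching aligned column (adjacent
mismatch columns stay separate events — the category is *simple*
substitution). Events are counted once each regardless of length; totals
are event counts, not discordant-base counts.

Classification rules, in order:

1. substitution column → `SUBSTITUTION`;
2. indel of k identical bases x whose flanking reference run of x has
   length ≥ 2 → `HP_INS_k` / `HP_DEL_k` (k ≤ 7), else `HP_*_GT7`. For a
   deletion the relevant run is the reference run containing the deleted
   bases; for an insertion, the run immediately adjacent to the insertion
   point on either side;
3. remaining length-1 indels → `INS_1` / `DEL_1`;
4. lengths 2–4 → `INS_SHORT` / `DEL_SHORT`;
5. length ≥ 5 → `INS_LONG` / `DEL_LONG`.

The published taxonomy names categories 1–4 and homopolymer
multiplicities 1–7; the `*_LONG` and `HP_*_GT7` categories exist so the
classifier is total, and are flagged "outside taxonomy" in reports.

Two readings of "homopolymer region ≥ 2 bases" are defensible: the run as
it exists in the *reference* before the edit, or the run as it exists
*after* the edit. The default is the reference reading — the reference is
the ground truth, so inserting an A next to a lone A is a single
insertion, not a homopolymer event. The alternative sits behind
`hp_criterion="resulting-run"`. Homopolymer runs are measured circularly
when the reference is circular (a run may span the origin).

Columns containing N are excluded by default (`count_ambiguous` counts
them as substitutions instead). An insertion run abutting a deletion run
remains two events; the taxonomy has no replacement category.

## p-distance

`p = differing sites / comparable sites` over alignment columns, where a
comparable site has a non-gap, non-N base in both rows (pairwise
deletion). Under this convention an indel-only discordance gives exactly
p = 0 — the discriminating test of the convention — and identical
sequences give 0 by construction. The alternative (`gaps-as-difference`)
counts gap columns as differing comparable sites; it is provided as a
switch because published per-assembly values cannot adjudicate the
convention without the original alignments. Aggregate statistics across
assemblies use the arithmetic mean and the sample (n−1) standard
deviation of the per-assembly error totals, rounded to 2 decimals only at
presentation time.

## ORF audit

Rather than re-annotating each assembly with external servers, reference
PCG coordinates are projected through the alignment onto assembly
coordinates: insertions strictly inside a gene extend its projection,
boundary insertions fall outside, deletions shrink it. Each projected
gene is translated in frame 0 of its interval (minus-strand genes
reverse-complemented first) under the vertebrate mitochondrial code
(NCBI translation table 2; stops TAA, TAG, AGA, AGG — the hard-coded set
is unit-tested against Biopython's table). `internal_stops` counts stop
codons strictly before the final codon; incomplete terminal codons are
ignored. A gene is *disrupted* iff it has an internal stop or its net
length change is not a multiple of 3, and counts as *not detected* when
its projection is shorter than 3 bp or below 50 % of the reference gene
length — a parameterized stand-in for annotation tools missing heavily
damaged short genes (the threshold is a modeling choice; no published
value exists for it). This measures the ORF-disruption proxy directly
and deterministically, not any particular annotation server's
heuristics.

## Synthetic data

The generator emulates the study conditions rather than any particular
genome:

* **Reference** (defaults: 16,705 bp, circular; GC 0.38; homopolymer
  target 0.45; 13 PCGs with canonical vertebrate mitochondrial lengths —
  including a short 168 bp *atp8* — 22 tRNAs of 70 bp, 2 rRNAs, a control
  region, 2 bp spacers; one PCG and every third tRNA on the minus
  strand). The sequence is drawn as a chain of identical-base runs: runs
  of length ≥ 2 (mean 2.3) occur with the probability that makes the
  expected fraction of sites inside ≥ 2 runs equal the `hp_fraction`
  target; run bases are drawn with weights fixed-point-corrected so the
  no-repeat run chain is stationary at the target GC. PCG intervals are
  then rewritten in place into valid ORFs (start ATG, terminal TAA,
  internal stops removed by third-position recoding), which perturbs the
  realized composition slightly; realized hp_fraction lands within
  ±0.05 of target (measured ~0.43) and GC within ~0.01. The first and
  last 40 bp are kept gene- and event-free so the rotation anchor is
  never damaged; the circular junction is kept run-free so run
  arithmetic never wraps in generated data.
* **Errors** are injected by exact count per category (count-based, not
  rate-based, because the benchmark's acceptance surface is exact
  recovery; a Poisson mode exists for stress tests). Each event is placed
  at a uniformly drawn locus satisfying its category's context —
  homopolymer events draw a run ≥ 2 length-weighted, mirroring the
  empirical concentration of miscounts at longer runs without modeling
  per-run-length rates for which no published estimates exist; single
  indels require a singleton-run context; short/long indels must not be
  all one base and must not be slide-able — and recorded in
  left-normalized form, so the truth set is exactly the canonical event
  list the pipeline should recover. Footprints are kept ≥ `min_spacing`
  (default 10 bp) apart, which prevents adjacent events from merging or
  re-aligning into each other during alignment. Rotation and
  reverse-complement are applied after injection and leave the truth
  untouched.

**What the simulator does not model:** clustered errors (real nanopore
errors interact within a few bases; `min_spacing` removes this on
purpose, because exact recovery would otherwise be ill-posed),
run-length-dependent error rates, coverage-dependent error structure,
chimeric or incomplete contigs, and ambiguity codes. Exact round-trip
recovery on simulator output therefore demonstrates that the pipeline
is lossless for well-separated events — not that it resolves every
adjacent-event ambiguity in real assemblies, where two close
opposite-sign indels can be score-equivalent to a run of substitutions.
The 100-seed recovery property tolerates one such failure per hundred
runs for exactly this reason.

## Numerical and degenerate-input choices

* Scores are IEEE doubles; the DP kernel's tie-break prefers
  match/mismatch over deletion over insertion, and the canonicalization
  step removes any residual placement arbitrariness.
* Alignment of sequences differing by more than 50 % in length is
  refused at the rotation stage; degenerate alignments with zero
  comparable columns make `p_distance` raise rather than return 0.
* Coordinates are 0-based half-open internally and 1-based in rendered
  reports. Annotation tracks may not wrap the circular origin; input
  with wrapped intervals is rejected with instructions to rotate the
  reference first (the generator guarantees non-wrapping tracks).
* Coverage is never computed (that would require read mapping); it is
  echoed from input metadata into reports.
* The compare path is entirely deterministic; all randomness lives in
  the synthetic-data module and requires an explicit seed.

## Problem sizes used by the shipped checks

The test suite and `scripts/acceptance.py` run the full pipeline on
full-size (16.7 kb) synthetic genomes — 100 seeds in the test suite's
round-trip property, 40 in the acceptance script — and validate the
numeric kernels against brute-force oracles on small instances (pairs
≤ 12–15 bp for alignment enumeration, 1,000 random gapped pairs for
p-distance, 20 rotations for the exhaustive rotation oracle). A compact
6 kb genome with 5 PCGs backs the alignment-heavy ORF and CLI tests.
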