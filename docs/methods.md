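# Methods

## The problem

A candidate RNA-editing site is an RNA-vs-reference substitution (in
fungi, typically A→G) supported by many RNA-seq reads.  Transcriptome-only
detection silently assumes the reference assembly is complete.  When two
near-identical genomic regions — transposon copies, tandem or segmental
duplications — are collapsed into a single reference locus, DNA *and* RNA
reads from both copies stack on that locus with perfect alignments, and
every position where the copies diverge masquerades as a high-confidence
RNA polymorphism.  A second artifact source is isolate mismatch: when the
DNA and RNA libraries come from different strains, genuine strain SNPs
appear as RNA-only variants.

`editcheck` re-evaluates candidate sites with the genomic evidence, in a
fixed precedence order:

1. **DNA match.**  Build a DNA pileup from the gDNA alignments; a
   candidate whose exact substitution (same site, same alternative base)
   is present in DNA at fraction > `dna_presence_frac` (default 5%,
   strict) is eliminated.  Collapsed duplications produce DNA variant
   fractions near 0.5 here, far above threshold.
2. **Absent on re-alignment.**  Re-align the same RNA reads
   independently (e.g. a newer spliced aligner with a realistic intron
   cap); a candidate no longer supported at calling thresholds is
   eliminated — its support was an alignment ambiguity.
3. **Pooled genomic match.**  Collapsed regions sometimes attract *no*
   DNA alignments at all, so step 1 cannot see them.  Search the raw,
   unaligned gDNA read pool for the variant-supporting RNA reads
   themselves: a candidate is eliminated when ≥ `min_hits` gDNA reads
   contain a supporting RNA read at 100% identity over the full length
   of the shorter sequence, with the match covering the variant base
   (forward or reverse-complement).
4. **Retained.**  Whatever survives is a credible editing candidate; if
   the manifest declares distinct DNA/RNA source strains, retained sites
   are flagged `possible_strain_variant`.

Every candidate receives exactly one category, so the per-sample counts
obey the conservation identity
`n_reported = n_dna_match + n_absent + n_pooled + n_retained`, which is
asserted on every run.

A complementary diagnostic maps candidate neighbourhoods through
genome-vs-genome alignment blocks into an independent reassembly:
sites whose flanking window corresponds to two well-separated regions in
the other assembly (`SPLIT_MULTI`) are collapse-explained directly.

## Candidate calling

Pileups are built by an explicit CIGAR walk: M/=/X place one query base
per reference position; I and S consume query only; D and N reference
only; H nothing.  Base N never counts as reference or variant support.
Reads matching the excluded-flag mask (default 1024, PCR/optical
duplicates) or below `min_mapq` are skipped.  A site is callable at
depth ≥ 20 reads; a non-reference base is called when supported by ≥ 5
reads and ≥ 10% of depth (all bounds inclusive; the DNA-presence bound
is strictly `> 5%`).  These are the only printed inequalities of the
procedure being re-implemented, and they are taken literally.
Insertions and deletions are out of scope; multiple passing alternative
bases at one site yield one call each; calls are reported in
reference-forward orientation without strand inference.

The vectorized pileup is validated against a per-read, per-base
expansion oracle on randomized alignment sets, and the k-mer-seeded
containment search against a naive O(pool × read) scan — both exact
agreements, not approximations.

## Read preprocessing

Order is fixed: exact full-length de-duplication → 3′ quality trimming →
length filter (< 40 bp dropped; 40 kept).  Trimming uses the
partial-sums rule: walking in from the 3′ end, accumulate
`(cutoff − q)` and cut where the running sum is maximal and strictly
positive, ties keeping the longest read.  This is the global-maximum
variant (no early break on a negative running sum), chosen because it is
exactly reproducible by brute force over all suffix cut points; it can
differ from break-on-negative implementations on quality profiles that
dip and recover.  5′ trimming and adapter removal are not performed;
synthetic reads carry no adapters.

## Pooled-read search details

"Full length of the shorter sequence" is the only containment notion
well-defined for unequal read lengths: an RNA read shorter than a gDNA
read must occur verbatim inside it, and vice versa, and in either case
the matched window must cover the variant base.  The implementation
indexes every k-mer (default k = 31) of every pool read; pool reads
shorter than k are kept aside and always checked directly, so the index
introduces no misses.  `min_hits` defaults to 1: one full-length exact
genomic match already demonstrates the allele exists in the genome.
The cost of that choice is quantified below under limitations.

## Liftover

A site lifts through every alignment block overlapping a ±75 bp window
(a short-read insert scale); its position is interpolated linearly
inside each block, mirrored for reverse-oriented blocks and clamped to
block ends.  Hits cluster into regions: different contigs, or same-contig
separation ≥ 10 kb (beyond tandem-repeat scale), count as separate.
One region → `UNIQUE`; two or more → `SPLIT_MULTI`; none → `UNMAPPED`.
Linear interpolation ignores indels inside blocks — acceptable at the
≥ 98% identity granularity of whole-genome alignment blocks, and the
reason window/gap sizes are configurable rather than load-bearing.

## The simulator

`SimConfig` defaults define the study conditions used throughout the
tests: 2 paralog pairs of 5 000 bp at 1% per-base divergence embedded in
a 13 000 bp collapsed contig (spacers ≥ one read length), 100 bp reads
at 60× per source copy, 0.5% uniform base error (constant Phred 23
qualities implied by that rate), 20 A→G edit sites at per-molecule rate
0.3, and 5 strain SNPs carried by the RNA-source isolate.  Collapsed
paralog loci therefore see ~120× from the two copies together, and each
divergent position has expected variant fraction 0.5.

Design choices worth stating:

- **Reads are placed, not aligned.**  Alignments are emitted directly
  from known provenance (copy-2 origins mapped onto copy-1
  coordinates), making artifacts deterministic and removing any aligner
  dependency.  Spliced RNA reads over the optional intron get M,N,M
  CIGARs.
- **Engineered sites sit in segment interiors** (≥ one read length from
  each edge) so they reach callable depth; edit sites are chosen on
  non-divergent A positions shared by both copies; strain SNPs are
  transitions applied to *both* copies at the same collapsed coordinate,
  so their expected RNA variant fraction is 1.0 and their truth label is
  unambiguous.
- **Single RNG.**  All randomness flows through one
  `numpy.random.default_rng` (PCG64) stream; a fixed seed reproduces
  every file byte-identically.
- **Withholding.**  `withhold_dna_alignment_for` removes a pair's DNA
  alignments (keeping its reads in the raw pool), emulating the
  uncovered-collapse case the pooled search exists for.  This scenario
  is exercised error-free and with strain mode off (`n_strain_snps=0`),
  because a strain SNP within one read length of a divergent site makes
  every variant-supporting RNA read differ from the DNA-isolate pool,
  so full-length exact matching legitimately fails — an isolate effect,
  not a search property.

What the simulator does **not** emulate: indels, GC/coverage bias,
paired-end structure, quality-score variation within reads, chimeric
reads, and polyploid genotypes.  Passing tests therefore demonstrate the
bookkeeping, thresholds and search semantics on idealized collapsed
duplications; they do not certify behaviour on real libraries with
structured error or bias.

## Numerical choices

- Coordinates are 0-based half-open internally and 1-based inclusive in
  every table; the shift happens only at I/O boundaries.
- Fraction thresholds compare exact integer ratios against the literal
  threshold values, so 5/50 passes ≥ 0.10 and 5/100 fails > 0.05
  without floating-point surprises.
- Removed-fraction percentages are rounded half-up to two decimals,
  matching the printed precision of the published per-sample table.
- Output ordering is everywhere (contig, position, alternative base)
  with stable sorts, so identical inputs give byte-identical tables.
- Degenerate inputs: reference base N yields no calls; zero-depth sites
  are absent from pileups and return an explicit zero-coverage marker;
  an empty gDNA pool or missing re-alignment skips that filter with a
  warning rather than inventing a verdict.

## Problem sizes used in the test suite

The default synthetic dataset (~23 kb true genome, ~26 000 reads) runs
the full pipeline in a few seconds; oracle comparisons use 100
randomized alignment sets of ≤ 50 reads and a 1 000-read pool.  These
sizes were chosen to make every property checkable by brute force while
keeping the whole suite fast on a laptop.

## Known limitations

- With `min_hits = 1`, a single gDNA read carrying one sequencing error
  at a genuine variant position can exactly reproduce a
  variant-supporting RNA read and eliminate a true site (observed at
  roughly one site per few simulated runs at 0.5% error and 120×
  collapsed depth).  Raising `min_hits` to 2 removes this mode at the
  cost of sensitivity in low-coverage pools.
- Paired-end mates are treated as independent records; there is no mate
  rescue and no fragment-level duplicate marking beyond the SAM flag.
- The realignment filter only consumes a *provided* second alignment; it
  does not run an aligner, so its discriminating power is exactly that
  of the supplied alignments.
- Liftover interpolation is collinear within blocks; sites inside large
  intra-block indels can shift by the indel length.
- External candidate lists are re-evaluated against the current
  alignments; a listed site that is covered but sub-threshold is classed
  absent-on-realignment, which conflates "never was real" with "support
  degraded" — the verdict evidence fields preserve the measured depth
  and fraction for downstream inspection.
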