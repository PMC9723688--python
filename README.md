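# editcheck

Misassembly-aware verification of candidate RNA-editing sites.

RNA-editing surveys call a site edited when many RNA-seq reads carry a
non-reference base (canonically A→G for A-to-I editing) at a genomic
position.  That inference silently assumes the reference assembly is
complete.  In practice, near-identical duplicated regions are often
*collapsed* into a single reference locus: DNA and RNA reads from both
copies then pile onto one place with perfect alignments, and every
position where the copies diverge looks exactly like a high-confidence
RNA polymorphism.  Strain mismatches between the DNA-sequenced and
RNA-sequenced isolates add a second class of spurious "edits".
`editcheck` is for genomicists who want to stress-test editing
candidates (their own, or a published list) against the genomic
evidence before believing them.

## Method

For each sample with RNA alignments, DNA alignments, and optionally a
second independent RNA alignment and the raw gDNA read pool:

1. **Candidate calling.**  Per-position base counts are accumulated by
   an explicit CIGAR walk (duplicate-flagged reads excluded).  A site
   with depth *d* ≥ 20 yields a candidate for every non-reference base
   *b* with count *c* ≥ 5 and variant allele fraction *c/d* ≥ 0.10.
2. **DNA match.**  Eliminate a candidate when the *same* substitution
   has DNA fraction > 5% at the site (collapsed duplications sit near
   50%).  Zero-DNA-coverage sites pass onward deliberately.
3. **Absent on re-alignment.**  Eliminate a candidate no longer
   supported at calling thresholds in the independent re-alignment.
4. **Pooled genomic match.**  Eliminate a candidate when ≥ `min_hits`
   raw gDNA reads contain one of its variant-supporting RNA reads at
   100% identity over the full length of the shorter sequence, covering
   the variant base (forward or reverse-complement; k-mer-indexed exact
   search).  This catches collapsed regions that attracted no DNA
   alignments at all.
5. **Retained** sites survive; with distinct DNA/RNA source strains
   declared they are flagged `possible_strain_variant`.

Each candidate gets exactly one category, so per-sample counts satisfy
`n_reported = n_dna_match + n_absent + n_pooled + n_retained`.
A liftover module additionally maps candidate neighbourhoods through
genome-vs-genome alignment blocks (show-coords tab format) and flags
sites whose window corresponds to two separated regions in an
independent reassembly — the direct signature of a collapse.

A first-class simulator (`editcheck.simulate`) generates the whole
artifact mechanism synthetically — a true genome with duplicated
segments, a collapsed reference keeping one copy, genuine per-molecule
A→G editing, strain SNPs, error-bearing reads, placed SAM alignments and
a ground-truth table — so the entire pipeline is testable without any
downloads.  See `docs/methods.md` for model details, parameter defaults
and limitations.

## Worked example

```python
import editcheck as ec

# default synthetic conditions: 2 collapsed 5-kb paralog pairs at 1%
# divergence, 60x per-copy coverage, 100-bp reads, 0.5% base error,
# 20 edit sites at rate 0.3, 5 strain SNPs
sim = ec.run_simulation(ec.SimConfig(seed=1))

thresholds = ec.CallerThresholds()
rna = ec.build_pileup(sim.rna_alignments, sim.collapsed_reference, thresholds, "demo", "RNA")
dna = ec.build_pileup(sim.gdna_alignments, sim.collapsed_reference, thresholds, "demo", "DNA")
calls = ec.call_candidates(rna, sim.collapsed_reference, thresholds)
pool, _ = ec.run_qc(sim.gdna_reads)
verdicts = ec.classify_sites(calls, dna, gdna_pool=pool,
                             rna_alignments=sim.rna_alignments.reads)
print(ec.summarize(verdicts, "demo").as_dict())
```

prints

```
{'sample_id': 'demo', 'n_reported': 125, 'n_dna_match': 100,
 'n_absent_realignment': 0, 'n_pooled_match': 0, 'n_retained': 25}
```

125 candidate sites enter filtering; the 100 paralog-divergence
artifacts are all eliminated by their matching DNA variants, and the 25
survivors are exactly the 20 engineered edit sites plus the 5 strain
SNPs.  A typical eliminated verdict looks like

```
SiteKey(contig='scaffold_1', pos=1103)  T->G  depth=121 alt=51
  category=DNA_MATCH  evidence={'dna_frac': 0.4048, 'dna_depth': 126}
```

— the RNA variant fraction ~0.42 and the DNA fraction ~0.40 are both the
half-and-half signature of two collapsed copies.

On the published per-sample summary of five Polyporales species (19
samples, shipped as a package fixture):

```python
report = ec.report_removed_fraction(ec.load_published_polyporales_summary())
print(report.min_pct, report.max_pct)   # 60.68 98.31
```

i.e. the DNA-match filter alone removed between 60.68% and 98.31% of
the previously reported editing sites per sample.

The same steps are available from the shell:

```bash
editcheck simulate --outdir fixtures/ --seed 1
editcheck call --ref fixtures/collapsed_ref.fa --aln fixtures/rna.sam --out calls.tsv
editcheck filter --calls calls.tsv --ref fixtures/collapsed_ref.fa \
    --rna fixtures/rna.sam --dna fixtures/gdna.sam --pool fixtures/gdna.fastq \
    --out verdicts.tsv
editcheck run --manifest samples.tsv --outdir results/   # multi-sample manifest
```

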