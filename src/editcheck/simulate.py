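"""Synthetic fixtures for the whole verification pipeline.

The simulator builds a haploid "true" genome in which each paralog pair
exists as two near-identical copies, and a *collapsed* reference that
keeps copy 1 only — the misassembly that makes reads from both copies
stack on one locus and mimic RNA polymorphism.  On top of that it plants
genuine A-to-G editing (per-molecule Bernoulli at a configurable rate)
and strain-difference SNPs carried only by the RNA-source isolate, then
samples error-bearing reads from both copies and *places* (rather than
aligns) them onto the collapsed reference, so every artifact is
deterministic and no external aligner is needed.

All randomness flows through one ``numpy.random.default_rng`` (PCG64)
stream seeded from ``SimConfig.seed``; identical configs give
byte-identical outputs.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io_core import (
    AlignedRead,
    ReadRecord,
    ReferenceGenome,
    SamData,
    SiteKey,
    revcomp,
    write_alignments,
    write_fasta,
    write_fastq,
)

PARALOG_ARTIFACT = "PARALOG_ARTIFACT"
TRUE_EDIT = "TRUE_EDIT"
STRAIN_SNP = "STRAIN_SNP"

BASES = "ACGT"
TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}

COLLAPSED_CONTIG = "scaffold_1"


@dataclass
class SimConfig:
    """Study conditions for one synthetic dataset.

    Depths are mean fold-coverage *per source copy*: a collapsed paralog
    locus therefore sees roughly twice the configured depth, as it would
    in a real collapsed assembly.  ``withhold_dna_alignment_for`` lists
    paralog-pair indices whose DNA alignments are dropped from the DNA
    SAM (but kept in the raw pool), emulating a collapsed region that
    attracted no genomic alignments.
    """

    genome_length: int = 13_000
    n_paralog_pairs: int = 2
    segment_length: int = 5_000
    divergence: float = 0.01
    n_edit_sites: int = 20
    edit_rate: float = 0.3
    n_strain_snps: int = 5
    dna_depth: float = 60.0
    rna_depth: float = 60.0
    read_length: int = 100
    error_rate: float = 0.005
    include_intron: bool = False
    intron_length: int = 500
    withhold_dna_alignment_for: tuple[int, ...] = ()
    seed: int = 1

    def __post_init__(self) -> None:
        for p in (self.divergence, self.edit_rate, self.error_rate):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.segment_length < 3 * self.read_length:
            raise ValueError("segment_length must be >= 3 * read_length")
        if min(self.dna_depth, self.rna_depth) < 1:
            raise ValueError("depths must be >= 1")
        if self.spacer_length < self.read_length:
            raise ValueError(
                "genome_length too small: spacers between segments must be "
                ">= read_length"
            )
        if any(i < 0 or i >= self.n_paralog_pairs for i in self.withhold_dna_alignment_for):
            raise ValueError("withheld pair index out of range")

    @property
    def spacer_length(self) -> int:
        n = self.n_paralog_pairs
        return (self.genome_length - n * self.segment_length) // (n + 1)

    @property
    def collapsed_length(self) -> int:
        n = self.n_paralog_pairs
        return n * self.segment_length + (n + 1) * self.spacer_length

    def segment_start(self, pair: int) -> int:
        """Copy-1 start of ``pair`` on the collapsed contig (0-based)."""
        return self.spacer_length * (pair + 1) + self.segment_length * pair

    @property
    def phred_quality(self) -> int:
        if self.error_rate <= 0:
            return 40
        return min(40, round(-10 * math.log10(self.error_rate)))


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth for one engineered site on the collapsed reference."""

    site: SiteKey
    truth_class: str
    ref_base: str
    alt_base: str
    expected_alt_frac: float


@dataclass
class PlacedRead:
    """A simulated read plus the provenance needed to place its alignment."""

    record: ReadRecord
    forward_sequence: str  # template orientation (errors applied)
    template: str  # "genome" | "transcript"
    contig: str  # true-genome contig, or transcript id
    pair: int  # paralog pair (-1 for genome background template)
    copy: int  # 1 or 2 for transcripts, 0 otherwise
    start: int  # offset in the template sequence
    strand: str  # "+" | "-"


@dataclass
class SimResult:
    config: SimConfig
    true_genome: ReferenceGenome
    collapsed_reference: ReferenceGenome
    strain_genome: ReferenceGenome
    truth: list[TruthRecord]
    gdna_reads: list[ReadRecord]
    rna_reads: list[ReadRecord]
    gdna_alignments: SamData
    rna_alignments: SamData
    gdna_pool: list[ReadRecord] = field(default_factory=list)

    def truth_by_class(self, truth_class: str) -> list[TruthRecord]:
        return [t for t in self.truth if t.truth_class == truth_class]


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, size=n))


def _other_base(rng: np.random.Generator, base: str) -> str:
    choices = [b for b in BASES if b != base]
    return choices[rng.integers(0, 3)]


class Simulator:
    """Stateful staged generator; see module docstring.

    Stages must run in order (``generate_genome`` -> ``simulate_reads``
    -> ``place_alignments``) because they share one RNG stream; ``run``
    does all three.
    """

    def __init__(self, config: SimConfig | None = None):
        self.config = config or SimConfig()
        self.rng = np.random.default_rng(self.config.seed)
        self.truth: list[TruthRecord] = []
        # per pair: dict offset -> copy2 base (segment coordinates)
        self.divergent: list[dict[int, str]] = []
        # per pair: sorted edit offsets (segment coordinates)
        self.edit_offsets: list[list[int]] = []
        self.snp_offsets: list[dict[int, str]] = []

    # -- stage 1 ----------------------------------------------------------

    def generate_genome(self) -> tuple[ReferenceGenome, ReferenceGenome, list[TruthRecord]]:
        cfg = self.config
        rng = self.rng
        L, rl = cfg.segment_length, cfg.read_length
        scaffold = _random_seq(rng, cfg.collapsed_length)

        if cfg.include_intron:
            istart = L // 2 - cfg.intron_length // 2
            iend = istart + cfg.intron_length
            if istart < rl or iend > L - rl:
                raise ValueError("intron does not fit inside the segment interior")
            self.intron = (istart, iend)
        else:
            self.intron = None

        copy2: list[str] = []
        for pair in range(cfg.n_paralog_pairs):
            s = cfg.segment_start(pair)
            copy1 = scaffold[s : s + L]
            n_div = int(rng.binomial(L, cfg.divergence))
            offsets = sorted(int(x) for x in rng.choice(L, size=n_div, replace=False))
            div = {}
            c2 = list(copy1)
            for off in offsets:
                alt = _other_base(rng, copy1[off])
                div[off] = alt
                c2[off] = alt
                self.truth.append(
                    TruthRecord(
                        SiteKey(COLLAPSED_CONTIG, s + off),
                        PARALOG_ARTIFACT,
                        copy1[off],
                        alt,
                        0.5,
                    )
                )
            self.divergent.append(div)
            copy2.append("".join(c2))

        # engineered-site pools: segment interiors only (>= one read length
        # from each edge) so every site can reach callable depth; exonic
        # only, and never colliding with a divergent position
        def eligible(pair: int, want_base: str | None) -> list[int]:
            s = cfg.segment_start(pair)
            out = []
            for off in range(rl, L - rl):
                if off in self.divergent[pair]:
                    continue
                if self.intron and self.intron[0] - rl < off < self.intron[1]:
                    continue  # intronic, or a read from exon1 would end inside
                if want_base is not None and scaffold[s + off] != want_base:
                    continue
                out.append(off)
            return out

        edit_pool = [(p, off) for p in range(cfg.n_paralog_pairs) for off in eligible(p, "A")]
        if cfg.n_edit_sites > len(edit_pool):
            raise ValueError("config infeasible: too many edit sites for the segments")
        picks = rng.choice(len(edit_pool), size=cfg.n_edit_sites, replace=False)
        chosen_edits = sorted(edit_pool[int(i)] for i in picks)
        self.edit_offsets = [[] for _ in range(cfg.n_paralog_pairs)]
        for pair, off in chosen_edits:
            self.edit_offsets[pair].append(off)
            self.truth.append(
                TruthRecord(
                    SiteKey(COLLAPSED_CONTIG, cfg.segment_start(pair) + off),
                    TRUE_EDIT,
                    "A",
                    "G",
                    cfg.edit_rate,
                )
            )

        taken = {(p, o) for p, o in chosen_edits}
        snp_pool = [
            (p, off)
            for p in range(cfg.n_paralog_pairs)
            for off in eligible(p, None)
            if (p, off) not in taken
        ]
        if cfg.n_strain_snps > len(snp_pool):
            raise ValueError("config infeasible: too many strain SNPs for the segments")
        picks = rng.choice(len(snp_pool), size=cfg.n_strain_snps, replace=False)
        self.snp_offsets = [{} for _ in range(cfg.n_paralog_pairs)]
        for p, off in sorted(snp_pool[int(i)] for i in picks):
            s = cfg.segment_start(p)
            ref = scaffold[s + off]
            alt = TRANSITION[ref]
            self.snp_offsets[p][off] = alt
            self.truth.append(
                TruthRecord(SiteKey(COLLAPSED_CONTIG, s + off), STRAIN_SNP, ref, alt, 1.0)
            )

        self.truth.sort(key=lambda t: (t.site.contig, t.site.pos))
        contigs = {COLLAPSED_CONTIG: scaffold}
        for pair, seq in enumerate(copy2):
            contigs[f"dup{pair + 1}"] = seq
        self.true_genome = ReferenceGenome(contigs)
        self.collapsed_reference = ReferenceGenome({COLLAPSED_CONTIG: scaffold})

        # the RNA-source isolate: strain SNPs applied to both paralog
        # copies at the same collapsed coordinate, so the expected RNA
        # variant fraction is 1.0
        strain = dict(contigs)
        sc = list(scaffold)
        for pair in range(cfg.n_paralog_pairs):
            s = cfg.segment_start(pair)
            d = list(strain[f"dup{pair + 1}"])
            for off, alt in self.snp_offsets[pair].items():
                sc[s + off] = alt
                d[off] = alt
            strain[f"dup{pair + 1}"] = "".join(d)
        strain[COLLAPSED_CONTIG] = "".join(sc)
        self.strain_genome = ReferenceGenome(strain)
        return self.true_genome, self.collapsed_reference, self.truth

    # -- stage 2 ----------------------------------------------------------

    def _transcript_seq(self, pair: int, copy: int) -> str:
        """Spliced transcript sequence from the RNA-source (strain) genome."""
        cfg = self.config
        if copy == 1:
            s = cfg.segment_start(pair)
            seg = self.strain_genome.contigs[COLLAPSED_CONTIG][s : s + cfg.segment_length]
        else:
            seg = self.strain_genome.contigs[f"dup{pair + 1}"]
        if self.intron:
            istart, iend = self.intron
            seg = seg[:istart] + seg[iend:]
        return seg

    def _transcript_edit_offsets(self, pair: int) -> list[int]:
        """Edit offsets in spliced-transcript coordinates."""
        if not self.intron:
            return list(self.edit_offsets[pair])
        istart, iend = self.intron
        ilen = iend - istart
        return [off if off < istart else off - ilen for off in self.edit_offsets[pair]]

    def _sample_reads(
        self,
        template_seq: str,
        n_reads: int,
        prefix: str,
        start_index: int,
        template: str,
        contig: str,
        pair: int,
        copy: int,
        edit_offsets: Sequence[int] = (),
    ) -> list[PlacedRead]:
        cfg = self.config
        rng = self.rng
        rl = cfg.read_length
        q = cfg.phred_quality
        out: list[PlacedRead] = []
        tlen = len(template_seq)
        for i in range(n_reads):
            start = int(rng.integers(0, tlen - rl + 1))
            bases = list(template_seq[start : start + rl])
            for off in edit_offsets:
                if start <= off < start + rl and rng.random() < cfg.edit_rate:
                    bases[off - start] = "G"
            if cfg.error_rate > 0:
                err = np.nonzero(rng.random(rl) < cfg.error_rate)[0]
                for j in err:
                    bases[j] = _other_base(rng, bases[j])
            fwd = "".join(bases)
            strand = "+" if rng.random() < 0.5 else "-"
            seq = fwd if strand == "+" else revcomp(fwd)
            rec = ReadRecord(f"{prefix}_{start_index + i:06d}", seq, [q] * rl)
            out.append(PlacedRead(rec, fwd, template, contig, pair, copy, start, strand))
        return out

    def simulate_reads(self) -> tuple[list[ReadRecord], list[ReadRecord]]:
        """Sample DNA reads from the true genome and RNA reads from the
        strain-genome transcripts; returns the raw read lists."""
        cfg = self.config
        rl = cfg.read_length
        self.placed_dna: list[PlacedRead] = []
        n = 0
        for contig, seq in self.true_genome.contigs.items():
            n_reads = int(round(cfg.dna_depth * len(seq) / rl))
            self.placed_dna.extend(
                self._sample_reads(seq, n_reads, "gdna", n, "genome", contig, -1, 0)
            )
            n += n_reads
        self.placed_rna: list[PlacedRead] = []
        n = 0
        for pair in range(cfg.n_paralog_pairs):
            t_edits = self._transcript_edit_offsets(pair)
            for copy in (1, 2):
                tseq = self._transcript_seq(pair, copy)
                n_reads = int(round(cfg.rna_depth * len(tseq) / rl))
                self.placed_rna.extend(
                    self._sample_reads(
                        tseq, n_reads, "rna", n, "transcript",
                        f"tx_p{pair}c{copy}", pair, copy, t_edits,
                    )
                )
                n += n_reads
        return (
            [p.record for p in self.placed_dna],
            [p.record for p in self.placed_rna],
        )

    # -- stage 3 ----------------------------------------------------------

    def _collapsed_placement(self, p: PlacedRead) -> tuple[int, list[tuple[int, str]]]:
        """(start, CIGAR) of a placed read on the collapsed reference."""
        cfg = self.config
        rl = cfg.read_length
        if p.template == "genome":
            if p.contig == COLLAPSED_CONTIG:
                return p.start, [(rl, "M")]
            pair = int(p.contig.removeprefix("dup")) - 1
            return cfg.segment_start(pair) + p.start, [(rl, "M")]
        # spliced transcript
        s = cfg.segment_start(p.pair)
        if not self.intron:
            return s + p.start, [(rl, "M")]
        istart, iend = self.intron
        ilen = iend - istart
        if p.start + rl <= istart:
            return s + p.start, [(rl, "M")]
        if p.start >= istart:
            return s + p.start + ilen, [(rl, "M")]
        a = istart - p.start
        return s + p.start, [(a, "M"), (ilen, "N"), (rl - a, "M")]

    def place_alignments(self) -> tuple[SamData, SamData]:
        """Emit DNA and RNA alignments on the collapsed reference directly
        from read provenance (no aligner involved).

        DNA reads overlapping a withheld pair's segment are omitted from
        the DNA alignments but stay in the raw pool.
        """
        cfg = self.config
        withheld = [
            (cfg.segment_start(i), cfg.segment_start(i) + cfg.segment_length)
            for i in cfg.withhold_dna_alignment_for
        ]

        def to_aligned(p: PlacedRead) -> AlignedRead:
            start, cigar = self._collapsed_placement(p)
            return AlignedRead(
                read_id=p.record.read_id,
                contig=COLLAPSED_CONTIG,
                start=start,
                cigar=cigar,
                sequence=p.forward_sequence,
                flags=16 if p.strand == "-" else 0,
                mapq=60,
                qualities=list(p.record.qualities or []),
            )

        dna: list[AlignedRead] = []
        for p in self.placed_dna:
            a = to_aligned(p)
            if any(a.start < hi and a.end > lo for lo, hi in withheld):
                continue
            dna.append(a)
        rna = [to_aligned(p) for p in self.placed_rna]
        self.gdna_alignments = SamData(dna)
        self.rna_alignments = SamData(rna)
        return self.gdna_alignments, self.rna_alignments

    # ----------------------------------------------------------------------

    def run(self) -> SimResult:
        self.generate_genome()
        gdna, rna = self.simulate_reads()
        self.place_alignments()
        return SimResult(
            config=self.config,
            true_genome=self.true_genome,
            collapsed_reference=self.collapsed_reference,
            strain_genome=self.strain_genome,
            truth=self.truth,
            gdna_reads=gdna,
            rna_reads=rna,
            gdna_alignments=self.gdna_alignments,
            rna_alignments=self.rna_alignments,
            gdna_pool=gdna,
        )


# ---------------------------------------------------------------------------
# Functional surface
# ---------------------------------------------------------------------------

def generate_genome(
    config: SimConfig,
) -> tuple[ReferenceGenome, ReferenceGenome, list[TruthRecord]]:
    """Generate (true genome, collapsed reference, truth records)."""
    return Simulator(config).generate_genome()


def simulate_reads(
    true_genome: ReferenceGenome, config: SimConfig
) -> tuple[list[ReadRecord], list[ReadRecord]]:
    """Regenerate the simulation deterministically from ``config`` and
    return (gDNA reads, RNA reads); ``true_genome`` must match the
    config's genome."""
    sim = Simulator(config)
    tg, _, _ = sim.generate_genome()
    if tg.contigs != true_genome.contigs:
        raise ValueError("true_genome does not match the config/seed")
    return sim.simulate_reads()


def write_truth(truth: Iterable[TruthRecord], path: str | Path) -> None:
    """Write ground truth as a TSV with 1-based positions, sorted by site."""
    rows = [
        {
            "contig": t.site.contig,
            "pos": t.site.pos + 1,
            "truth_class": t.truth_class,
            "ref": t.ref_base,
            "alt": t.alt_base,
            "expected_alt_frac": t.expected_alt_frac,
        }
        for t in truth
    ]
    df = pd.DataFrame(
        rows, columns=["contig", "pos", "truth_class", "ref", "alt", "expected_alt_frac"]
    )
    df = df.sort_values(["contig", "pos"], kind="mergesort")
    df.to_csv(path, sep="\t", index=False)


def read_truth(path: str | Path) -> pd.DataFrame:
    """Read a truth TSV back with 0-based positions."""
    df = pd.read_csv(path, sep="\t")
    df["pos"] = df["pos"].astype(int) - 1
    return df


def run_simulation(config: SimConfig | None = None, outdir: str | Path | None = None) -> SimResult:
    """Run all stages; optionally write the fixture files to ``outdir``
    (true_genome.fa, collapsed_ref.fa, gdna.fastq, rna.fastq, gdna.sam,
    rna.sam, truth.tsv, config.json)."""
    result = Simulator(config).run()
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(result.true_genome, outdir / "true_genome.fa")
        write_fasta(result.collapsed_reference, outdir / "collapsed_ref.fa")
        write_fastq(result.gdna_reads, outdir / "gdna.fastq")
        write_fastq(result.rna_reads, outdir / "rna.fastq")
        write_alignments(result.gdna_alignments, result.collapsed_reference, outdir / "gdna.sam")
        write_alignments(result.rna_alignments, result.collapsed_reference, outdir / "rna.sam")
        write_truth(result.truth, outdir / "truth.tsv")
        with open(outdir / "config.json", "w") as fh:
            json.dump(asdict(result.config), fh, indent=2, default=list)
    return result
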