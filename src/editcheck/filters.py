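"""The three elimination filters and precedence-ordered site classification.

A candidate RNA variant is explained away, in fixed precedence order, by:

1. ``DNA_MATCH`` — the same substitution is present in the genomic-DNA
   read alignment at a fraction strictly above the presence threshold
   (default 5%).  Collapsed duplications and real genomic polymorphism
   both land here.
2. ``ABSENT_IN_REALIGNMENT`` — an independent re-alignment of the same
   RNA reads (e.g. a newer spliced aligner with an intron-length cap) no
   longer supports the variant at calling thresholds.
3. ``POOLED_GENOMIC_MATCH`` — at least one raw genomic read contains a
   variant-supporting RNA read at 100% identity over the full length of
   the shorter sequence, covering the variant base; this rescues the case
   where the collapsed region attracted no DNA alignments at all.

Whatever survives is ``RETAINED`` — a credible editing candidate, or a
strain difference when DNA and RNA came from different isolates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .io_core import AlignedRead, ReadRecord, revcomp
from .pileup_caller import CallerThresholds, Pileup, VariantCall, site_fraction

log = logging.getLogger("editcheck")

DNA_MATCH = "DNA_MATCH"
ABSENT_IN_REALIGNMENT = "ABSENT_IN_REALIGNMENT"
POOLED_GENOMIC_MATCH = "POOLED_GENOMIC_MATCH"
RETAINED = "RETAINED"
CATEGORIES = (DNA_MATCH, ABSENT_IN_REALIGNMENT, POOLED_GENOMIC_MATCH, RETAINED)


@dataclass
class SiteVerdict:
    """Exactly one filtering category per candidate call, with evidence."""

    call: VariantCall
    category: str
    evidence: dict = field(default_factory=dict)
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")

    def to_row(self) -> dict:
        row = self.call.to_row()
        row["category"] = self.category
        row["evidence"] = ";".join(f"{k}={v}" for k, v in sorted(self.evidence.items()))
        row["flags"] = ",".join(self.flags)
        return row


@dataclass
class PooledSearchParams:
    """Exact-containment search over the raw genomic read pool."""

    kmer_size: int = 31
    min_hits: int = 1
    search_revcomp: bool = True

    def __post_init__(self) -> None:
        if self.kmer_size < 11:
            raise ValueError("kmer_size must be >= 11")
        if self.min_hits < 1:
            raise ValueError("min_hits must be >= 1")


# ---------------------------------------------------------------------------
# Filter 1: matching variant in the gDNA read alignment
# ---------------------------------------------------------------------------

def filter_dna_match(
    rna_calls: Sequence[VariantCall],
    dna_pileup: Pileup,
    thresholds: CallerThresholds | None = None,
) -> tuple[list[SiteVerdict], list[VariantCall]]:
    """Partition calls into (DNA-matched verdicts, surviving calls).

    A call matches when the *same* alternative base at the same site has a
    DNA fraction strictly greater than ``dna_presence_frac``.  A different
    substitution type at the site does not match, and a site with zero DNA
    coverage is deliberately passed onward (the pooled-read search is the
    remedy for uncovered collapsed regions).
    """
    thresholds = thresholds or CallerThresholds()
    matched: list[SiteVerdict] = []
    surviving: list[VariantCall] = []
    for call in rna_calls:
        sf = site_fraction(dna_pileup, call.site, call.alt_base)
        if sf.covered and sf.frac > thresholds.dna_presence_frac:
            matched.append(
                SiteVerdict(
                    call,
                    DNA_MATCH,
                    {"dna_frac": round(sf.frac, 4), "dna_depth": sf.depth},
                )
            )
        else:
            surviving.append(call)
    return matched, surviving


# ---------------------------------------------------------------------------
# Filter 2: variant absent when the reads are re-aligned independently
# ---------------------------------------------------------------------------

def filter_absent_in_realignment(
    calls: Sequence[VariantCall],
    second_rna_pileup: Pileup | None,
    thresholds: CallerThresholds | None = None,
) -> tuple[list[SiteVerdict], list[VariantCall]]:
    """Partition calls into (absent-on-realignment verdicts, survivors).

    A call is absent when, in the second pileup, the site/alt no longer
    satisfies the calling thresholds (insufficient depth, alternative
    count, or fraction).  With no second pileup the filter is skipped and
    every call passes through.
    """
    thresholds = thresholds or CallerThresholds()
    if second_rna_pileup is None:
        log.warning("no independent re-alignment supplied; realignment filter skipped")
        return [], list(calls)
    absent: list[SiteVerdict] = []
    surviving: list[VariantCall] = []
    for call in calls:
        bc = second_rna_pileup.get(call.site)
        depth = bc.depth
        alt_reads = bc.count(call.alt_base)
        frac = alt_reads / depth if depth else 0.0
        still_called = (
            depth >= thresholds.min_depth
            and alt_reads >= thresholds.min_alt_reads
            and frac >= thresholds.min_alt_frac
        )
        if still_called:
            surviving.append(call)
        else:
            absent.append(
                SiteVerdict(
                    call,
                    ABSENT_IN_REALIGNMENT,
                    {"realign_depth": depth, "realign_frac": round(frac, 4)},
                )
            )
    return absent, surviving


# ---------------------------------------------------------------------------
# Filter 3: full-length exact match in the pooled raw gDNA reads
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Containment:
    """A pool read matching ``query[q_start:q_end]`` at 100% identity over
    the full length of the shorter sequence (query coordinates, forward
    orientation of the query)."""

    pool_read_id: str
    q_start: int
    q_end: int


class PooledReadIndex:
    """k-mer index over a raw read pool supporting exact shorter-in-longer
    containment queries.

    The index stores every k-mer of every pool read.  Pool reads shorter
    than k cannot be seeded and are always checked directly, so results
    are identical to a naive full scan.
    """

    def __init__(self, pool: Sequence[ReadRecord], params: PooledSearchParams | None = None):
        self.params = params or PooledSearchParams()
        self.reads = list(pool)
        k = self.params.kmer_size
        self.index: dict[str, list[int]] = {}
        self.short_read_idx: list[int] = []
        for i, r in enumerate(self.reads):
            seq = r.sequence
            if len(seq) < k:
                self.short_read_idx.append(i)
                continue
            seen_here = set()
            for j in range(len(seq) - k + 1):
                kmer = seq[j : j + k]
                if kmer not in seen_here:
                    self.index.setdefault(kmer, []).append(i)
                    seen_here.add(kmer)

    def _candidates(self, oriented: str) -> Iterable[int]:
        k = self.params.kmer_size
        if len(oriented) < k:
            return range(len(self.reads))  # brute scan, query unseedable
        cand: set[int] = set(self.short_read_idx)
        for j in range(len(oriented) - k + 1):
            cand.update(self.index.get(oriented[j : j + k], ()))
        return cand

    def containments(self, query: str) -> list[Containment]:
        """All pool reads containing / contained in ``query`` exactly.

        For a pool read at least as long as the query, the whole query
        must occur verbatim (window = whole query).  For a shorter pool
        read, it must occur verbatim inside the query; every occurrence
        window is reported.  The reverse complement of the query is also
        searched when enabled, with windows mapped back to forward query
        coordinates.
        """
        out: list[Containment] = []
        orientations = [(query, False)]
        if self.params.search_revcomp:
            orientations.append((revcomp(query), True))
        qlen = len(query)
        seen: set[tuple[str, int, int]] = set()
        for oriented, is_rc in orientations:
            for i in self._candidates(oriented):
                g = self.reads[i].sequence
                if len(oriented) <= len(g):
                    if oriented in g:
                        windows = [(0, len(oriented))]
                    else:
                        windows = []
                else:
                    windows = []
                    p = oriented.find(g)
                    while p != -1:
                        windows.append((p, p + len(g)))
                        p = oriented.find(g, p + 1)
                for lo, hi in windows:
                    if is_rc:
                        lo, hi = qlen - hi, qlen - lo
                    key = (self.reads[i].read_id, lo, hi)
                    if key not in seen:
                        seen.add(key)
                        out.append(Containment(self.reads[i].read_id, lo, hi))
        return out


def supporting_reads(
    calls: Sequence[VariantCall], rna_alignments: Iterable[AlignedRead]
) -> dict[tuple[str, int, str], list[tuple[AlignedRead, int]]]:
    """For each call, the aligned RNA reads whose base at the site equals
    the alternative base, with the query offset of that base."""
    by_contig: dict[str, list[VariantCall]] = {}
    for c in calls:
        by_contig.setdefault(c.site.contig, []).append(c)
    support: dict[tuple[str, int, str], list[tuple[AlignedRead, int]]] = {
        c.key: [] for c in calls
    }
    for read in rna_alignments:
        for call in by_contig.get(read.contig, ()):
            if not (read.start <= call.site.pos < read.end):
                continue
            hit = read.base_at(call.site.pos)
            if hit is not None and hit[0] == call.alt_base:
                support[call.key].append((read, hit[1]))
    return support


def pooled_genomic_search(
    calls: Sequence[VariantCall],
    rna_alignments: Iterable[AlignedRead],
    gdna_pool: Sequence[ReadRecord],
    params: PooledSearchParams | None = None,
) -> tuple[list[SiteVerdict], list[VariantCall]]:
    """Partition calls into (pooled-match verdicts, survivors).

    A call matches when at least ``min_hits`` distinct pool reads contain
    one of its variant-supporting RNA reads at 100% identity over the
    full length of the shorter sequence, with the containment window
    covering the variant base.  An empty pool skips the filter.
    """
    params = params or PooledSearchParams()
    calls = list(calls)
    if not gdna_pool:
        log.warning("empty gDNA read pool; pooled-read filter skipped")
        return [], calls
    index = PooledReadIndex(gdna_pool, params)
    support = supporting_reads(calls, rna_alignments)
    cache: dict[str, list[Containment]] = {}
    matched: list[SiteVerdict] = []
    surviving: list[VariantCall] = []
    for call in calls:
        hits: set[str] = set()
        for read, qpos in support[call.key]:
            conts = cache.get(read.read_id)
            if conts is None:
                conts = index.containments(read.sequence)
                cache[read.read_id] = conts
            for c in conts:
                if c.q_start <= qpos < c.q_end:
                    hits.add(c.pool_read_id)
        if len(hits) >= params.min_hits:
            matched.append(
                SiteVerdict(call, POOLED_GENOMIC_MATCH, {"n_pool_reads": len(hits)})
            )
        else:
            surviving.append(call)
    return matched, surviving


# ---------------------------------------------------------------------------
# Precedence-ordered classification
# ---------------------------------------------------------------------------

def classify_sites(
    rna_calls: Sequence[VariantCall],
    dna_pileup: Pileup,
    second_rna_pileup: Pileup | None = None,
    gdna_pool: Sequence[ReadRecord] | None = None,
    rna_alignments: Iterable[AlignedRead] | None = None,
    thresholds: CallerThresholds | None = None,
    pooled_params: PooledSearchParams | None = None,
) -> list[SiteVerdict]:
    """Apply the three filters in precedence order; every input call gets
    exactly one category and survivors are RETAINED.

    The pooled-read search requires the RNA alignments (to collect
    variant-supporting reads); without them, or with an empty pool, it is
    skipped.
    """
    thresholds = thresholds or CallerThresholds()
    dna_matched, rest = filter_dna_match(rna_calls, dna_pileup, thresholds)
    absent, rest = filter_absent_in_realignment(rest, second_rna_pileup, thresholds)
    if gdna_pool and rna_alignments is not None:
        pooled, rest = pooled_genomic_search(rest, rna_alignments, gdna_pool, pooled_params)
    else:
        if gdna_pool and rna_alignments is None:
            log.warning("gDNA pool given without RNA alignments; pooled filter skipped")
        pooled = []
    retained = [SiteVerdict(c, RETAINED) for c in rest]
    verdicts = dna_matched + absent + pooled + retained
    verdicts.sort(key=lambda v: (v.call.site.contig, v.call.site.pos, v.call.alt_base))
    assert len(verdicts) == len(rna_calls)
    return verdicts
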