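"""Per-position base counts from alignments and threshold-based variant calling.

This replaces the external two-sample caller with a transparent pileup walk:
reads are filtered by SAM flag mask (duplicates, flag 1024, by default) and
mapping quality, their CIGARs are walked so that M/=/X place one query base
per reference position, I/S consume query only, D/N reference only, and H
nothing.  Base N never counts as reference or variant support.

Candidate sites follow the printed inequalities exactly: a site is callable
when depth >= 20 mapped reads, and a non-reference base is reported when it
is supported by >= 5 reads and >= 10% of the depth; a genomic allele "match"
downstream means a DNA fraction strictly greater than 5%.  Insertions and
deletions are never called.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .io_core import AlignedRead, ReferenceGenome, SamData, SiteKey

BASES = "ACGT"

# byte value -> base index (A/C/G/T -> 0..3, everything else 255)
_BASE_LUT = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _BASE_LUT[ord(_b)] = _i
    _BASE_LUT[ord(_b.lower())] = _i


def _seq_to_idx(seq: str) -> np.ndarray:
    return _BASE_LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclass
class CallerThresholds:
    """Calling and matching thresholds.

    ``min_depth``/``min_alt_reads``/``min_alt_frac`` gate RNA candidate
    calls (inclusive bounds); ``dna_presence_frac`` is the strict lower
    bound on the DNA variant fraction that counts as a genomic match;
    ``excluded_flag_mask`` drops flagged reads (1024 = PCR/optical
    duplicate) and ``min_mapq`` the low-mapping-quality ones.
    """

    min_depth: int = 20
    min_alt_reads: int = 5
    min_alt_frac: float = 0.10
    dna_presence_frac: float = 0.05
    excluded_flag_mask: int = 1024
    min_mapq: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.min_alt_frac <= 1 and 0 <= self.dna_presence_frac <= 1):
            raise ValueError("fractions must lie in [0, 1]")
        if self.min_depth < 1:
            raise ValueError("min_depth must be >= 1")


@dataclass(frozen=True)
class BaseCounts:
    """Counts of the four bases at one position; depth is their sum."""

    count_A: int = 0
    count_C: int = 0
    count_G: int = 0
    count_T: int = 0

    @property
    def depth(self) -> int:
        return self.count_A + self.count_C + self.count_G + self.count_T

    def count(self, base: str) -> int:
        return getattr(self, f"count_{base}")


@dataclass
class Pileup:
    """Per-contig (length x 4) base-count arrays for one alignment set."""

    sample_id: str
    source: str  # "RNA" | "DNA"
    counts: dict[str, np.ndarray]
    n_reads_used: int = 0
    n_reads_skipped: int = 0

    def get(self, site: SiteKey) -> BaseCounts:
        arr = self.counts.get(site.contig)
        if arr is None:
            return BaseCounts()
        row = arr[site.pos]
        return BaseCounts(int(row[0]), int(row[1]), int(row[2]), int(row[3]))

    def depth(self, site: SiteKey) -> int:
        arr = self.counts.get(site.contig)
        return int(arr[site.pos].sum()) if arr is not None else 0


@dataclass(frozen=True)
class VariantCall:
    """One candidate substitution at one site."""

    site: SiteKey
    ref_base: str
    alt_base: str
    depth: int
    alt_count: int
    sample_id: str = ""
    source: str = "RNA"

    def __post_init__(self) -> None:
        if self.ref_base == self.alt_base:
            raise ValueError("ref_base == alt_base")
        if self.alt_count > self.depth:
            raise ValueError("alt_count exceeds depth")

    @property
    def alt_frac(self) -> float:
        return self.alt_count / self.depth if self.depth else 0.0

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.site.contig, self.site.pos, self.alt_base)

    def to_row(self) -> dict:
        return {
            "contig": self.site.contig,
            "pos": self.site.pos,
            "ref": self.ref_base,
            "alt": self.alt_base,
            "depth": self.depth,
            "alt_count": self.alt_count,
            "alt_frac": round(self.alt_frac, 4),
        }


@dataclass(frozen=True)
class SiteFraction:
    """Variant fraction and depth at one site; ``covered`` is False when the
    site has zero aligned bases (an explicit zero-coverage marker)."""

    frac: float
    depth: int
    covered: bool


def build_pileup(
    alignments: SamData | Iterable[AlignedRead],
    reference: ReferenceGenome,
    thresholds: CallerThresholds | None = None,
    sample_id: str = "",
    source: str = "RNA",
) -> Pileup:
    """Accumulate per-position base counts over all eligible reads.

    Reads matching ``excluded_flag_mask`` or below ``min_mapq`` are
    skipped.  A read placed on a contig absent from (or beyond the end of)
    the reference raises ``ValueError``.
    """
    thresholds = thresholds or CallerThresholds()
    counts = {
        name: np.zeros((len(seq), 4), dtype=np.int32)
        for name, seq in reference.contigs.items()
    }
    used = skipped = 0
    for read in alignments:
        if (read.flags & thresholds.excluded_flag_mask) or read.mapq < thresholds.min_mapq:
            skipped += 1
            continue
        arr = counts.get(read.contig)
        if arr is None:
            raise ValueError(f"read {read.read_id!r} aligned to unknown contig {read.contig!r}")
        if read.end > arr.shape[0]:
            raise ValueError(
                f"read {read.read_id!r} extends past the end of contig {read.contig!r}"
            )
        idx = _seq_to_idx(read.sequence)
        rpos, qpos = read.start, 0
        for n, op in read.cigar:
            if op in "M=X":
                seg = idx[qpos : qpos + n]
                valid = seg < 4  # N observations are discarded
                if valid.all():
                    np.add.at(arr, (np.arange(rpos, rpos + n), seg), 1)
                else:
                    positions = np.arange(rpos, rpos + n)[valid]
                    np.add.at(arr, (positions, seg[valid]), 1)
                rpos += n
                qpos += n
            elif op in "IS":
                qpos += n
            elif op in "DN":
                rpos += n
        used += 1
    return Pileup(sample_id, source, counts, used, skipped)


def call_candidates(
    pileup: Pileup,
    reference: ReferenceGenome,
    thresholds: CallerThresholds | None = None,
) -> list[VariantCall]:
    """Call every (site, alt base) passing the depth/count/fraction gates.

    Multiple passing alternative bases at one site yield one call each;
    sites whose reference base is N are never called.  Output is ordered by
    (reference contig order, position, alt base) and is deterministic.
    """
    thresholds = thresholds or CallerThresholds()
    calls: list[VariantCall] = []
    for contig, seq in reference.contigs.items():
        arr = pileup.counts.get(contig)
        if arr is None:
            continue
        depth = arr.sum(axis=1)
        deep = depth >= thresholds.min_depth
        if not deep.any():
            continue
        ref_idx = _seq_to_idx(seq)
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = arr / np.maximum(depth, 1)[:, None]
        for b in range(4):
            cnt = arr[:, b]
            mask = (
                deep
                & (ref_idx != b)
                & (ref_idx < 4)
                & (cnt >= thresholds.min_alt_reads)
                & (frac[:, b] >= thresholds.min_alt_frac)
            )
            for pos in np.nonzero(mask)[0]:
                calls.append(
                    VariantCall(
                        site=SiteKey(contig, int(pos)),
                        ref_base=seq[pos],
                        alt_base=BASES[b],
                        depth=int(depth[pos]),
                        alt_count=int(cnt[pos]),
                        sample_id=pileup.sample_id,
                        source=pileup.source,
                    )
                )
    calls.sort(key=lambda c: (list(reference.contigs).index(c.site.contig), c.site.pos, c.alt_base))
    return calls


def site_fraction(pileup: Pileup, site: SiteKey, alt_base: str) -> SiteFraction:
    """Variant fraction of ``alt_base`` at ``site`` with its depth.

    A site with zero aligned bases returns ``SiteFraction(0.0, 0, covered=False)``.
    """
    bc = pileup.get(site)
    if bc.depth == 0:
        return SiteFraction(0.0, 0, False)
    return SiteFraction(bc.count(alt_base) / bc.depth, bc.depth, True)
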