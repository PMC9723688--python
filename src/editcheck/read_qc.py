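"""Read preprocessing: exact de-duplication, 3' quality trimming, length filter.

The fixed preprocessing order is deduplicate -> quality_trim -> length_filter.
Trimming uses the partial-sums rule: walking in from the 3' end, accumulate
(cutoff - q) per base and cut at the position where the running sum is
maximal and positive; a read whose qualities all meet the cutoff is left
untouched.  De-duplication is by exact full-length sequence identity (no
reverse-complement collapsing, no mate awareness).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from .io_core import ReadRecord


@dataclass
class QcParams:
    """Quality cutoff (Phred) and minimum retained read length (bases)."""

    quality_cutoff: int = 20
    min_length: int = 40

    def __post_init__(self) -> None:
        if self.quality_cutoff < 0:
            raise ValueError("quality_cutoff must be >= 0")
        if self.min_length < 1:
            raise ValueError("min_length must be >= 1")


@dataclass
class QcSummary:
    n_in: int = 0
    n_out: int = 0
    n_duplicates: int = 0
    n_too_short: int = 0
    bases_trimmed: int = 0

    def as_dict(self) -> dict:
        return {
            "reads_in": self.n_in,
            "reads_out": self.n_out,
            "duplicates_removed": self.n_duplicates,
            "too_short_removed": self.n_too_short,
            "bases_trimmed": self.bases_trimmed,
        }


def deduplicate(reads: Iterable[ReadRecord]) -> tuple[list[ReadRecord], int]:
    """Keep the first occurrence of every exact full-length sequence.

    Returns (kept reads, number dropped).  Reads of different lengths are
    never duplicates of each other; the operation is idempotent.
    """
    seen: set[str] = set()
    kept: list[ReadRecord] = []
    dropped = 0
    for r in reads:
        if r.sequence in seen:
            dropped += 1
        else:
            seen.add(r.sequence)
            kept.append(r)
    return kept, dropped


def trim_point(qualities: list[int], cutoff: int) -> int:
    """3' cut index: keep ``read[:i]`` where the suffix sum of (cutoff - q)
    over ``read[i:]`` is maximal and strictly positive; ties keep the
    longest read."""
    best = 0
    cut = len(qualities)
    running = 0
    for i in range(len(qualities) - 1, -1, -1):
        running += cutoff - qualities[i]
        if running > best:
            best = running
            cut = i
    return cut


def quality_trim(read: ReadRecord, params: QcParams) -> ReadRecord:
    """Trim low-quality 3' tails by the partial-sums rule.

    Raises ``ValueError`` for reads without qualities (FASTA input bypasses
    trimming at the pipeline level).
    """
    if read.qualities is None:
        raise ValueError(f"read {read.read_id!r} has no base qualities")
    cut = trim_point(read.qualities, params.quality_cutoff)
    if cut == len(read.sequence):
        return read
    return ReadRecord(read.read_id, read.sequence[:cut], read.qualities[:cut])


def length_filter(reads: Iterable[ReadRecord], params: QcParams) -> list[ReadRecord]:
    """Drop reads shorter than ``min_length`` (strict: a read of exactly
    ``min_length`` bases is kept)."""
    return [r for r in reads if len(r) >= params.min_length]


def run_qc(
    reads: Iterable[ReadRecord], params: QcParams | None = None
) -> tuple[list[ReadRecord], QcSummary]:
    """Full preprocessing: deduplicate, 3'-trim (when qualities are present),
    then length-filter.  Returns the surviving reads and a summary."""
    params = params or QcParams()
    reads = list(reads)
    summary = QcSummary(n_in=len(reads))
    kept, summary.n_duplicates = deduplicate(reads)
    trimmed: list[ReadRecord] = []
    for r in kept:
        if r.qualities is None:
            trimmed.append(r)
            continue
        t = quality_trim(r, params)
        summary.bases_trimmed += len(r) - len(t)
        trimmed.append(t)
    out = length_filter(trimmed, params)
    summary.n_too_short = len(trimmed) - len(out)
    summary.n_out = len(out)
    return out, summary
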