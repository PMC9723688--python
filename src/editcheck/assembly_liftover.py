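"""Cross-assembly site mapping and collapse detection.

A candidate site on the old assembly is lifted through genome-vs-genome
alignment blocks: every block overlapping a flanking window contributes a
hit, hits are clustered into regions, and a site whose neighbourhood maps
to two or more well-separated regions (``SPLIT_MULTI``) is the signature
of a duplication that the old assembly collapsed into one copy.
Interpolation inside a block assumes collinearity (no indel-aware
offsetting), a documented approximation acceptable at high block identity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .io_core import CoordsBlock, SiteKey
from .pileup_caller import VariantCall

UNIQUE = "UNIQUE"
SPLIT_MULTI = "SPLIT_MULTI"
UNMAPPED = "UNMAPPED"


@dataclass
class LiftoverParams:
    """``window``: bases flanking the site on each side that must overlap a
    block for it to contribute; ``split_gap``: minimum separation (bases) in
    the new assembly for two hits to count as separate regions (different
    contigs always separate)."""

    window: int = 75
    split_gap: int = 10_000

    def __post_init__(self) -> None:
        if self.window < 1 or self.split_gap < 1:
            raise ValueError("window and split_gap must be >= 1")


@dataclass(frozen=True)
class LiftoverHit:
    new_contig: str
    new_pos: int  # 0-based
    pct_identity: float


@dataclass
class LiftoverResult:
    site: SiteKey
    hits: list[LiftoverHit]
    status: str
    n_regions: int


def _interpolate(block: CoordsBlock, pos1: int) -> int:
    """Linearly interpolate a 1-based old position into the new interval,
    mirrored for reverse blocks, clamped to the block ends."""
    b = block
    os_, oe = (b.old_start, b.old_end) if b.old_start <= b.old_end else (b.old_end, b.old_start)
    ns, ne = (b.new_start, b.new_end) if b.old_start <= b.old_end else (b.new_end, b.new_start)
    t = (pos1 - os_) / (oe - os_)
    t = min(1.0, max(0.0, t))
    return round(ns + t * (ne - ns))


def _cluster_regions(hits: Sequence[LiftoverHit], split_gap: int) -> int:
    by_contig: dict[str, list[int]] = {}
    for h in hits:
        by_contig.setdefault(h.new_contig, []).append(h.new_pos)
    regions = 0
    for positions in by_contig.values():
        positions.sort()
        regions += 1
        for prev, cur in zip(positions, positions[1:]):
            if cur - prev >= split_gap:
                regions += 1
    return regions


def map_site(
    blocks: Iterable[CoordsBlock], site: SiteKey, params: LiftoverParams | None = None
) -> LiftoverResult:
    """Lift one old-assembly site through the alignment blocks.

    Status is UNIQUE (exactly one distinct region), SPLIT_MULTI (two or
    more regions separated by ``split_gap`` or on different contigs), or
    UNMAPPED (no block overlaps the flanking window).  Independent of
    block input order.
    """
    params = params or LiftoverParams()
    pos1 = site.pos + 1
    lo, hi = pos1 - params.window, pos1 + params.window
    hits: list[LiftoverHit] = []
    for b in blocks:
        if b.old_contig != site.contig:
            continue
        os_, oe = (b.old_start, b.old_end) if b.old_start <= b.old_end else (b.old_end, b.old_start)
        if os_ <= hi and oe >= lo:
            hits.append(LiftoverHit(b.new_contig, _interpolate(b, pos1) - 1, b.pct_identity))
    hits.sort(key=lambda h: (h.new_contig, h.new_pos, -h.pct_identity))
    if not hits:
        return LiftoverResult(site, [], UNMAPPED, 0)
    n = _cluster_regions(hits, params.split_gap)
    return LiftoverResult(site, hits, UNIQUE if n == 1 else SPLIT_MULTI, n)


def lift_sites(
    blocks: Sequence[CoordsBlock],
    sites: Iterable[SiteKey],
    params: LiftoverParams | None = None,
) -> dict[SiteKey, LiftoverResult]:
    return {s: map_site(blocks, s, params) for s in sites}


@dataclass
class VariantSetDiff:
    """Cross-assembly comparison of two candidate-call sets.

    ``collapse_explained``: old calls whose neighbourhood maps to multiple
    separate new regions.  ``eliminated_by_reassembly``: old calls whose
    unique image carries no matching new call.  ``assembly_introduced``:
    new calls at positions that are not the image of any old call.
    ``persistent`` and ``unmapped_old`` complete the partition of the old
    calls; no call appears in two categories.
    """

    eliminated_by_reassembly: list[VariantCall] = field(default_factory=list)
    collapse_explained: list[VariantCall] = field(default_factory=list)
    assembly_introduced: list[VariantCall] = field(default_factory=list)
    persistent: list[VariantCall] = field(default_factory=list)
    unmapped_old: list[VariantCall] = field(default_factory=list)


def diff_variant_sets(
    old_calls: Sequence[VariantCall],
    new_calls: Sequence[VariantCall],
    liftover_results: Mapping[SiteKey, LiftoverResult],
) -> VariantSetDiff:
    """Compare old- and new-assembly call sets through a liftover.

    An old UNIQUE call "matches" a new call when the image position carries
    a call with the same alternative base.
    """
    diff = VariantSetDiff()
    new_by_key = {(c.site.contig, c.site.pos, c.alt_base) for c in new_calls}
    image_positions: set[tuple[str, int]] = set()
    for call in old_calls:
        res = liftover_results[call.site]
        if res.status == UNMAPPED:
            diff.unmapped_old.append(call)
            continue
        for h in res.hits:
            image_positions.add((h.new_contig, h.new_pos))
        if res.status == SPLIT_MULTI:
            diff.collapse_explained.append(call)
        else:
            h = res.hits[0]
            if (h.new_contig, h.new_pos, call.alt_base) in new_by_key:
                diff.persistent.append(call)
            else:
                diff.eliminated_by_reassembly.append(call)
    for call in new_calls:
        if (call.site.contig, call.site.pos) not in image_positions:
            diff.assembly_introduced.append(call)
    return diff
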