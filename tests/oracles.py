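"""Independent brute-force oracles used to validate the optimized paths."""

from collections import Counter

from editcheck import AlignedRead, CallerThresholds, ReferenceGenome, revcomp


def naive_pileup_counts(reads, thresholds: CallerThresholds) -> dict:
    """Per-read, per-base expansion: walk each CIGAR one base at a time and
    tally A/C/G/T observations per (contig, position)."""
    counts: dict[tuple[str, int], Counter] = {}
    for read in reads:
        if (read.flags & thresholds.excluded_flag_mask) or read.mapq < thresholds.min_mapq:
            continue
        rpos, qpos = read.start, 0
        for n, op in read.cigar:
            if op in "M=X":
                for i in range(n):
                    base = read.sequence[qpos + i]
                    if base in "ACGT":
                        counts.setdefault((read.contig, rpos + i), Counter())[base] += 1
                rpos += n
                qpos += n
            elif op in "IS":
                qpos += n
            elif op in "DN":
                rpos += n
    return counts


def brute_force_trim_point(qualities, cutoff) -> int:
    """Try every suffix cut point; keep the prefix whose removed suffix has
    the maximal positive sum of (cutoff - q), preferring the longest read."""
    best_cut = len(qualities)
    best_sum = 0
    for cut in range(len(qualities), -1, -1):
        s = sum(cutoff - q for q in qualities[cut:])
        if s > best_sum:
            best_sum = s
            best_cut = cut
    return best_cut


def naive_containment_scan(query: str, pool, search_revcomp: bool = True) -> set:
    """O(pool x read) exact shorter-in-longer scan; returns
    {(pool_read_id, q_start, q_end)} in forward query coordinates."""
    out = set()
    orientations = [(query, False)]
    if search_revcomp:
        orientations.append((revcomp(query), True))
    for rec in pool:
        g = rec.sequence
        for oriented, is_rc in orientations:
            if len(oriented) <= len(g):
                windows = [(0, len(oriented))] if oriented in g else []
            else:
                windows = []
                p = oriented.find(g)
                while p != -1:
                    windows.append((p, p + len(g)))
                    p = oriented.find(g, p + 1)
            for lo, hi in windows:
                if is_rc:
                    lo, hi = len(query) - hi, len(query) - lo
                out.add((rec.read_id, lo, hi))
    return out


def random_alignments(rng, reference: ReferenceGenome, n_reads: int) -> list[AlignedRead]:
    """Random but valid alignments with mixed CIGARs over a reference."""
    names = list(reference.contigs)
    reads = []
    for i in range(n_reads):
        contig = names[rng.integers(0, len(names))]
        clen = reference.length(contig)
        start = int(rng.integers(0, max(1, clen - 30)))
        cigar = []
        rspan = 0
        if rng.random() < 0.3:
            cigar.append((int(rng.integers(1, 5)), "S"))
        n_segments = int(rng.integers(1, 4))
        for j in range(n_segments):
            mlen = int(rng.integers(1, 12))
            cigar.append((mlen, "M"))
            rspan += mlen
            if j < n_segments - 1:
                op = "IDN"[rng.integers(0, 3)]
                olen = int(rng.integers(1, 8))
                cigar.append((olen, op))
                if op in "DN":
                    rspan += olen
        if rng.random() < 0.3:
            cigar.append((int(rng.integers(1, 5)), "S"))
        if start + rspan > clen:
            start = max(0, clen - rspan)
            if start + rspan > clen:
                continue
        qlen = sum(n for n, op in cigar if op in "MIS")
        seq = "".join("ACGTN"[k] for k in rng.integers(0, 5, size=qlen))
        flags = 1024 if rng.random() < 0.15 else (16 if rng.random() < 0.5 else 0)
        mapq = int(rng.integers(0, 61))
        reads.append(
            AlignedRead(f"r{i}", contig, start, cigar, seq, flags=flags, mapq=mapq)
        )
    return reads
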