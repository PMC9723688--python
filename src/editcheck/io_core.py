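"""Readers, writers and shared coordinate/sequence types.

Everything downstream of this module works in 0-based half-open
coordinates; every user-facing table renders positions 1-based.  SAM is
consumed and produced through :mod:`pysam`, FASTA/FASTQ through
Biopython, site tables through pandas.  The tab-separated ``show-coords``
dialect (genome-vs-genome alignment blocks) has no established parser
and is parsed here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import pandas as pd
import pysam
from Bio import SeqIO

log = logging.getLogger("editcheck")

COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: CIGAR operations that consume query bases.
QUERY_OPS = frozenset("M=XIS")
#: CIGAR operations that consume reference bases.
REF_OPS = frozenset("M=XDN")
#: CIGAR operations that place a query base on a reference position.
ALIGN_OPS = frozenset("M=X")
KNOWN_OPS = frozenset("M=XIDNSH")

_CIGAR_OP_CHARS = "MIDNSHP=X"


class FormatError(ValueError):
    """A structured problem in an input file (names the offending record)."""


def revcomp(seq: str) -> str:
    """Reverse complement of an A/C/G/T/N sequence."""
    return seq.translate(COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# Reference genomes (FASTA)
# ---------------------------------------------------------------------------

@dataclass
class ReferenceGenome:
    """An assembly held fully in memory as uppercase sequences.

    ``contigs`` preserves file order; names are unique and non-empty,
    sequences non-empty over the A/C/G/T/N alphabet.
    """

    contigs: dict[str, str]

    def __post_init__(self) -> None:
        for name, seq in self.contigs.items():
            if not name:
                raise FormatError("empty contig name")
            if not seq:
                raise FormatError(f"contig {name!r} has an empty sequence")

    def __contains__(self, name: str) -> bool:
        return name in self.contigs

    def __iter__(self) -> Iterator[str]:
        return iter(self.contigs)

    def length(self, contig: str) -> int:
        return len(self.contigs[contig])

    def base(self, contig: str, pos: int) -> str:
        """Reference base at a 0-based position."""
        return self.contigs[contig][pos]

    def fetch(self, contig: str, start: int, end: int) -> str:
        return self.contigs[contig][start:end]


def read_fasta(path: str | Path) -> ReferenceGenome:
    """Load a (possibly multi-line, mixed-case) FASTA file.

    Raises :class:`FormatError` on duplicate contig names or empty records.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    contigs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in contigs:
            raise FormatError(f"duplicate contig name {rec.id!r} in {path}")
        seq = str(rec.seq).upper()
        if not seq:
            raise FormatError(f"contig {rec.id!r} in {path} is empty")
        contigs[rec.id] = seq
    return ReferenceGenome(contigs)


def write_fasta(genome: ReferenceGenome, path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.contigs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Raw reads (FASTQ / FASTA)
# ---------------------------------------------------------------------------

@dataclass
class ReadRecord:
    """One sequencing read; ``qualities`` is absent for FASTA input."""

    read_id: str
    sequence: str
    qualities: list[int] | None = None

    def __post_init__(self) -> None:
        if self.qualities is not None and len(self.qualities) != len(self.sequence):
            raise FormatError(
                f"read {self.read_id!r}: {len(self.qualities)} quality values "
                f"for {len(self.sequence)} bases"
            )

    def __len__(self) -> int:
        return len(self.sequence)


def read_reads(path: str | Path, fmt: str | None = None) -> list[ReadRecord]:
    """Read a FASTQ (Phred+33) or FASTA file of raw reads.

    The format is taken from the extension unless ``fmt`` is given
    (``"fastq"`` or ``"fasta"``).
    """
    path = Path(path)
    if fmt is None:
        fmt = "fastq" if path.suffix.lower() in {".fastq", ".fq"} else "fasta"
    reads = []
    for rec in SeqIO.parse(str(path), fmt):
        quals = rec.letter_annotations.get("phred_quality")
        reads.append(
            ReadRecord(rec.id, str(rec.seq).upper(), list(quals) if quals is not None else None)
        )
    return reads


def write_fastq(reads: Iterable[ReadRecord], path: str | Path) -> None:
    """Write reads as 4-line FASTQ records, Phred+33 (quality 2 for FASTA input)."""
    with open(path, "w") as fh:
        for r in reads:
            quals = r.qualities if r.qualities is not None else [2] * len(r.sequence)
            qual = "".join(chr(q + 33) for q in quals)
            fh.write(f"@{r.read_id}\n{r.sequence}\n+\n{qual}\n")


# ---------------------------------------------------------------------------
# Alignments (SAM)
# ---------------------------------------------------------------------------

@dataclass
class AlignedRead:
    """One mapped SAM record with its CIGAR decomposed into (length, op)."""

    read_id: str
    contig: str
    start: int  # 0-based reference position
    cigar: list[tuple[int, str]]
    sequence: str
    flags: int = 0
    mapq: int = 60
    qualities: list[int] | None = None

    def __post_init__(self) -> None:
        for _, op in self.cigar:
            if op not in KNOWN_OPS:
                raise FormatError(f"read {self.read_id!r}: unknown CIGAR op {op!r}")
        qlen = sum(n for n, op in self.cigar if op in QUERY_OPS)
        if qlen != len(self.sequence):
            raise FormatError(
                f"read {self.read_id!r}: CIGAR consumes {qlen} query bases "
                f"but sequence has {len(self.sequence)}"
            )
        if self.start < 0:
            raise FormatError(f"read {self.read_id!r}: negative start")

    @property
    def reference_span(self) -> int:
        return sum(n for n, op in self.cigar if op in REF_OPS)

    @property
    def end(self) -> int:
        """One past the last reference position covered (0-based half-open)."""
        return self.start + self.reference_span

    def aligned_pairs(self) -> Iterator[tuple[int, int]]:
        """Yield (reference_pos, query_pos) for every aligned (M/=/X) base."""
        rpos, qpos = self.start, 0
        for n, op in self.cigar:
            if op in ALIGN_OPS:
                for i in range(n):
                    yield rpos + i, qpos + i
                rpos += n
                qpos += n
            elif op in "IS":
                qpos += n
            elif op in "DN":
                rpos += n
        # H consumes nothing

    def base_at(self, refpos: int) -> tuple[str, int] | None:
        """Query base placed on ``refpos``, with its query offset, or None."""
        if not (self.start <= refpos < self.end):
            return None
        rpos, qpos = self.start, 0
        for n, op in self.cigar:
            if op in ALIGN_OPS:
                if rpos <= refpos < rpos + n:
                    q = qpos + (refpos - rpos)
                    return self.sequence[q], q
                rpos += n
                qpos += n
            elif op in "IS":
                qpos += n
            elif op in "DN":
                if rpos <= refpos < rpos + n:
                    return None  # deletion / skip over the position
                rpos += n
        return None


@dataclass
class SamData:
    """Mapped records from one SAM file plus the count of skipped unmapped ones."""

    reads: list[AlignedRead]
    n_unmapped: int = 0

    def __iter__(self) -> Iterator[AlignedRead]:
        return iter(self.reads)

    def __len__(self) -> int:
        return len(self.reads)


def _reraise_parse_errors(records, path: Path):
    """Convert htslib parse failures into FormatError naming the record."""
    while True:
        try:
            rec = next(records)
        except StopIteration:
            return
        except OSError:
            raise FormatError(
                f"{path}: malformed SAM record: {_locate_sam_defect(path)}"
            ) from None
        yield rec


def _locate_sam_defect(path: Path) -> str:
    """Best-effort description of the first malformed SAM data line
    (htslib aborts without naming it)."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("@") or not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 11:
                return f"line {lineno}: fewer than 11 fields"
            qname, cigar, seq = fields[0], fields[5], fields[9]
            if cigar == "*" or seq == "*":
                continue
            qlen = 0
            num = ""
            for ch in cigar:
                if ch.isdigit():
                    num += ch
                elif num:
                    if ch in "MIS=X":
                        qlen += int(num)
                    num = ""
                else:
                    return f"read {qname!r} (line {lineno}): bad CIGAR {cigar!r}"
            if qlen != len(seq):
                return (
                    f"read {qname!r} (line {lineno}): CIGAR consumes {qlen} "
                    f"query bases but sequence has {len(seq)}"
                )
    return "unknown defect"


def read_alignments(path: str | Path) -> SamData:
    """Parse a headered SAM file into :class:`AlignedRead` records.

    Unmapped records (flag 0x4) are skipped and counted.  CIGAR/sequence
    length mismatches and unknown CIGAR operations raise
    :class:`FormatError` identifying the read.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    reads: list[AlignedRead] = []
    n_unmapped = 0
    with pysam.AlignmentFile(str(path), "r") as sam:
        try:
            records = iter(sam)
        except OSError as exc:  # pragma: no cover - header-level failure
            raise FormatError(f"{path}: {exc}") from None
        for rec in _reraise_parse_errors(records, path):
            if rec.is_unmapped:
                n_unmapped += 1
                continue
            cigar = [
                (length, _CIGAR_OP_CHARS[op]) for op, length in (rec.cigartuples or [])
            ]
            quals = rec.query_qualities
            reads.append(
                AlignedRead(
                    read_id=rec.query_name,
                    contig=rec.reference_name,
                    start=rec.reference_start,
                    cigar=cigar,
                    sequence=(rec.query_sequence or "").upper(),
                    flags=rec.flag,
                    mapq=rec.mapping_quality,
                    qualities=list(quals) if quals is not None else None,
                )
            )
    if n_unmapped:
        log.debug("%s: skipped %d unmapped records", path, n_unmapped)
    return SamData(reads, n_unmapped)


def write_alignments(
    reads: Iterable[AlignedRead], reference: ReferenceGenome, path: str | Path
) -> None:
    """Write reads as a headered SAM file against ``reference``."""
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": name, "LN": len(seq)} for name, seq in reference.contigs.items()],
    }
    with pysam.AlignmentFile(str(path), "w", header=header) as sam:
        for r in reads:
            seg = pysam.AlignedSegment(sam.header)
            seg.query_name = r.read_id
            seg.flag = r.flags
            seg.reference_id = sam.header.get_tid(r.contig)
            seg.reference_start = r.start
            seg.mapping_quality = r.mapq
            seg.cigartuples = [
                (_CIGAR_OP_CHARS.index(op), n) for n, op in r.cigar
            ]
            seg.query_sequence = r.sequence
            if r.qualities is not None:
                seg.query_qualities = pysam.qualitystring_to_array(
                    "".join(chr(q + 33) for q in r.qualities)
                )
            sam.write(seg)


# ---------------------------------------------------------------------------
# Sites and site tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True, order=True)
class SiteKey:
    """A single reference position (0-based internally, 1-based in tables)."""

    contig: str
    pos: int


SITE_TABLE_COLUMNS = [
    "contig", "pos", "ref", "alt", "depth", "alt_count", "alt_frac",
]


def write_sites_table(records: Sequence, path: str | Path) -> None:
    """Write calls or verdicts as a TSV with 1-based positions.

    Each record must provide ``to_row()`` returning a mapping with at least
    the :data:`SITE_TABLE_COLUMNS` keys (``pos`` 0-based; shifted here).
    Rows are ordered by (contig, pos, alt).
    """
    rows = [dict(r.to_row()) for r in records]
    for row in rows:
        row["pos"] = row["pos"] + 1
    columns = list(SITE_TABLE_COLUMNS)
    extra = [k for k in (rows[0] if rows else {}) if k not in columns]
    columns += extra
    df = pd.DataFrame(rows, columns=columns)
    df = df.sort_values(["contig", "pos", "alt"], kind="mergesort")
    df.to_csv(path, sep="\t", index=False)


def read_sites_table(path: str | Path) -> pd.DataFrame:
    """Read a site TSV; '#'-prefixed comment lines are ignored.

    The 1-based ``pos`` column is shifted back to the internal 0-based
    convention.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    for col in ("contig", "pos", "ref", "alt"):
        if col not in df.columns:
            raise FormatError(f"{path}: site table lacks required column {col!r}")
    df["pos"] = df["pos"].astype(int) - 1
    return df


# ---------------------------------------------------------------------------
# Genome-vs-genome alignment blocks (show-coords tab dialect)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CoordsBlock:
    """One old->new assembly alignment block (1-based inclusive intervals).

    ``new_start > new_end`` encodes reverse orientation.
    """

    old_contig: str
    old_start: int
    old_end: int
    new_contig: str
    new_start: int
    new_end: int
    pct_identity: float

    def __post_init__(self) -> None:
        if self.old_start == self.old_end or self.new_start == self.new_end:
            raise FormatError("degenerate alignment block")
        if not (0 < self.pct_identity <= 100):
            raise FormatError(f"identity {self.pct_identity} outside (0, 100]")

    @property
    def is_reverse(self) -> bool:
        return self.new_start > self.new_end


_HEADER_PREFIXES = ("#", "[", "=", "/", "NUCMER")


def read_coords(path: str | Path) -> list[CoordsBlock]:
    """Parse a tab/space-separated show-coords style file.

    Expected data columns: old_start old_end new_start new_end old_len
    new_len pct_identity old_contig new_contig.  Header and rule lines are
    tolerated and skipped; a non-numeric coordinate in a data row raises
    :class:`FormatError` with the line number.
    """
    path = Path(path)
    blocks: list[CoordsBlock] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(_HEADER_PREFIXES):
                continue
            fields = line.split()
            if len(fields) < 9:
                continue  # tolerated header / banner line
            try:
                os_, oe, ns, ne = (int(x) for x in fields[:4])
                ident = float(fields[6])
            except ValueError as exc:
                raise FormatError(
                    f"{path}:{lineno}: non-numeric coordinate field ({exc})"
                ) from None
            blocks.append(
                CoordsBlock(
                    old_contig=fields[7],
                    old_start=os_,
                    old_end=oe,
                    new_contig=fields[8],
                    new_start=ns,
                    new_end=ne,
                    pct_identity=ident,
                )
            )
    n_rev = sum(b.is_reverse for b in blocks)
    if n_rev:
        log.debug("%s: %d of %d blocks reverse-oriented", path, n_rev, len(blocks))
    return blocks
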