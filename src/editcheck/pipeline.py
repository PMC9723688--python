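"""Multi-sample orchestration, summary bookkeeping, and removed-fraction stats.

A run is driven by a tab-separated manifest (one sample per row).  For
each sample the pipeline builds RNA and DNA pileups, calls candidates
(or re-evaluates an externally supplied site list), classifies every
candidate through the precedence-ordered filters, and emits one summary
row whose category counts always sum back to the number of candidates
entering filtering — the conservation identity that the published
per-sample tables obey.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from pathlib import Path
from typing import Sequence

import pandas as pd

from .filters import (
    ABSENT_IN_REALIGNMENT,
    DNA_MATCH,
    POOLED_GENOMIC_MATCH,
    RETAINED,
    PooledSearchParams,
    SiteVerdict,
    classify_sites,
)
from .io_core import (
    SiteKey,
    read_alignments,
    read_fasta,
    read_reads,
    read_sites_table,
    write_sites_table,
)
from .pileup_caller import CallerThresholds, VariantCall, build_pileup, call_candidates
from .read_qc import QcParams, run_qc

log = logging.getLogger("editcheck")

STRAIN_FLAG = "possible_strain_variant"


@dataclass
class Sample:
    """One manifest row; all paths must exist when the run starts."""

    sample_id: str
    reference: Path
    rna_sam: Path
    dna_sam: Path
    rna2_sam: Path | None = None
    pool: Path | None = None
    coords: Path | None = None
    sites: Path | None = None
    dna_strain: str | None = None
    rna_strain: str | None = None
    realignment_max_intron_bp: int = 2000

    @property
    def different_strains(self) -> bool:
        return bool(
            self.dna_strain and self.rna_strain and self.dna_strain != self.rna_strain
        )


_MANIFEST_PATHS = ("reference", "rna_sam", "dna_sam", "rna2_sam", "pool", "coords", "sites")


def read_manifest(path: str | Path) -> list[Sample]:
    """Read a manifest TSV; relative paths resolve against the manifest's
    directory.  Duplicate sample ids or missing files are errors."""
    path = Path(path)
    base = path.parent
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if "sample_id" not in df.columns:
        raise ValueError(f"{path}: manifest lacks a sample_id column")
    samples: list[Sample] = []
    seen: set[str] = set()
    for _, row in df.iterrows():
        sid = row["sample_id"]
        if sid in seen:
            raise ValueError(f"{path}: duplicate sample_id {sid!r}")
        seen.add(sid)
        kwargs: dict = {"sample_id": sid}
        for col in _MANIFEST_PATHS:
            val = row.get(col)
            if pd.isna(val) or val in (None, ""):
                continue
            p = Path(val)
            if not p.is_absolute():
                p = base / p
            if not p.exists():
                raise FileNotFoundError(f"{path}: sample {sid!r}: {p} does not exist")
            kwargs[col] = p
        for col in ("dna_strain", "rna_strain"):
            val = row.get(col)
            if not pd.isna(val) and val:
                kwargs[col] = val
        val = row.get("realignment_max_intron_bp")
        if val is not None and not pd.isna(val):
            kwargs["realignment_max_intron_bp"] = int(val)
        for required in ("reference", "rna_sam", "dna_sam"):
            if required not in kwargs:
                raise ValueError(f"{path}: sample {sid!r} lacks {required}")
        samples.append(Sample(**kwargs))
    return samples


@dataclass
class SummaryRow:
    """Per-sample category bookkeeping (the published-table row shape)."""

    sample_id: str
    n_reported: int
    n_dna_match: int
    n_absent_realignment: int
    n_pooled_match: int
    n_retained: int

    def __post_init__(self) -> None:
        total = (
            self.n_dna_match
            + self.n_absent_realignment
            + self.n_pooled_match
            + self.n_retained
        )
        if total != self.n_reported:
            raise ValueError(
                f"sample {self.sample_id!r}: category counts sum to {total}, "
                f"not n_reported={self.n_reported}"
            )

    def as_dict(self) -> dict:
        return asdict(self)


def summarize(verdicts: Sequence[SiteVerdict], sample_id: str = "") -> SummaryRow:
    """Count verdict categories; the conservation identity is enforced."""
    counts = {c: 0 for c in (DNA_MATCH, ABSENT_IN_REALIGNMENT, POOLED_GENOMIC_MATCH, RETAINED)}
    for v in verdicts:
        counts[v.category] += 1
    return SummaryRow(
        sample_id=sample_id,
        n_reported=len(verdicts),
        n_dna_match=counts[DNA_MATCH],
        n_absent_realignment=counts[ABSENT_IN_REALIGNMENT],
        n_pooled_match=counts[POOLED_GENOMIC_MATCH],
        n_retained=counts[RETAINED],
    )


def _external_calls(
    sites_path: Path, rna_pileup, sample_id: str
) -> list[VariantCall]:
    """Re-express an externally supplied candidate list against the current
    RNA pileup (depth and variant count recomputed from the alignments)."""
    df = read_sites_table(sites_path)
    calls = []
    for _, row in df.iterrows():
        site = SiteKey(str(row["contig"]), int(row["pos"]))
        bc = rna_pileup.get(site)
        calls.append(
            VariantCall(
                site=site,
                ref_base=str(row["ref"]),
                alt_base=str(row["alt"]),
                depth=bc.depth,
                alt_count=bc.count(str(row["alt"])),
                sample_id=sample_id,
                source="RNA",
            )
        )
    return calls


def run_sample(
    sample: Sample,
    thresholds: CallerThresholds | None = None,
    pooled_params: PooledSearchParams | None = None,
    qc_params: QcParams | None = None,
) -> tuple[list[SiteVerdict], SummaryRow]:
    """Run one sample: pileups -> candidates -> classification -> summary.

    With an external site list, candidates are the listed sites re-evaluated
    against the current pileups; a site no longer supported at calling
    thresholds in the provided RNA alignments (including zero coverage)
    classifies as ABSENT_IN_REALIGNMENT unless a genomic match takes
    precedence.  Retained sites are flagged ``possible_strain_variant``
    when the manifest declares distinct DNA/RNA source strains.
    """
    thresholds = thresholds or CallerThresholds()
    reference = read_fasta(sample.reference)
    rna = read_alignments(sample.rna_sam)
    rna_pileup = build_pileup(rna, reference, thresholds, sample.sample_id, "RNA")
    dna = read_alignments(sample.dna_sam)
    dna_pileup = build_pileup(dna, reference, thresholds, sample.sample_id, "DNA")
    rna2_pileup = None
    if sample.rna2_sam is not None:
        rna2 = read_alignments(sample.rna2_sam)
        rna2_pileup = build_pileup(rna2, reference, thresholds, sample.sample_id, "RNA")
    pool = None
    if sample.pool is not None:
        pool, qc_summary = run_qc(read_reads(sample.pool), qc_params)
        log.info("sample %s: gDNA pool QC %s", sample.sample_id, qc_summary.as_dict())

    if sample.sites is not None:
        calls = _external_calls(sample.sites, rna_pileup, sample.sample_id)
        second = rna2_pileup if rna2_pileup is not None else rna_pileup
    else:
        calls = call_candidates(rna_pileup, reference, thresholds)
        second = rna2_pileup
    log.info("sample %s: %d candidate sites enter filtering", sample.sample_id, len(calls))
    verdicts = classify_sites(
        calls,
        dna_pileup,
        second_rna_pileup=second,
        gdna_pool=pool,
        rna_alignments=rna.reads,
        thresholds=thresholds,
        pooled_params=pooled_params,
    )
    if sample.different_strains:
        for v in verdicts:
            if v.category == RETAINED:
                v.flags.append(STRAIN_FLAG)
    row = summarize(verdicts, sample.sample_id)
    log.info("sample %s: %s", sample.sample_id, row.as_dict())
    return verdicts, row


@dataclass
class RunResult:
    summary: pd.DataFrame
    verdicts: dict[str, list[SiteVerdict]]
    failures: dict[str, str] = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return not self.failures


def run_pipeline(
    manifest: str | Path | Sequence[Sample],
    thresholds: CallerThresholds | None = None,
    pooled_params: PooledSearchParams | None = None,
    outdir: str | Path | None = None,
) -> RunResult:
    """Run every manifest sample; per-sample failures are isolated and
    reported while manifest-level problems raise immediately.

    With ``outdir``, writes per-sample ``<id>.verdicts.tsv``, a global
    ``summary.tsv``, ``removed_fraction.tsv`` and ``run_params.json``.
    """
    if isinstance(manifest, (str, Path)):
        samples = read_manifest(manifest)
    else:
        samples = list(manifest)
    thresholds = thresholds or CallerThresholds()
    pooled_params = pooled_params or PooledSearchParams()
    rows: list[SummaryRow] = []
    verdicts: dict[str, list[SiteVerdict]] = {}
    failures: dict[str, str] = {}
    for sample in samples:
        try:
            v, row = run_sample(sample, thresholds, pooled_params)
        except Exception as exc:  # noqa: BLE001 - isolate per-sample failures
            log.error("sample %s failed: %s", sample.sample_id, exc)
            failures[sample.sample_id] = str(exc)
            continue
        verdicts[sample.sample_id] = v
        rows.append(row)
    summary = pd.DataFrame([r.as_dict() for r in rows])
    result = RunResult(summary, verdicts, failures)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for sid, v in verdicts.items():
            write_sites_table(v, outdir / f"{sid}.verdicts.tsv")
        summary.to_csv(outdir / "summary.tsv", sep="\t", index=False)
        if len(summary):
            report = report_removed_fraction(summary)
            report.table.to_csv(outdir / "removed_fraction.tsv", sep="\t", index=False)
        with open(outdir / "run_params.json", "w") as fh:
            json.dump(
                {
                    "thresholds": asdict(thresholds),
                    "pooled_search": asdict(pooled_params),
                    "failures": failures,
                },
                fh,
                indent=2,
            )
    return result


# ---------------------------------------------------------------------------
# Removed-fraction statistics and the published comparison table
# ---------------------------------------------------------------------------

def _round2(x: Decimal) -> float:
    return float(x.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass
class RemovedFractionReport:
    """Per-row percent of candidates removed by the genomic-match filter,
    with the min and max across rows."""

    table: pd.DataFrame
    min_pct: float
    max_pct: float


def report_removed_fraction(
    rows: pd.DataFrame | Sequence[SummaryRow],
) -> RemovedFractionReport:
    """percent = 100 * n_dna_match / n_reported, half-up to 2 decimals.

    Rows with ``n_reported == 0`` are excluded with a warning.
    """
    if not isinstance(rows, pd.DataFrame):
        rows = pd.DataFrame([r.as_dict() for r in rows])
    df = rows.copy()
    zero = df["n_reported"].astype(int) == 0
    if zero.any():
        log.warning("%d rows with zero reported sites excluded", int(zero.sum()))
        df = df[~zero]
    if df.empty:
        raise ValueError("no rows with n_reported > 0")
    pcts = [
        _round2(Decimal(100) * Decimal(int(m)) / Decimal(int(n)))
        for m, n in zip(df["n_dna_match"], df["n_reported"])
    ]
    df = df.assign(removed_pct=pcts)
    return RemovedFractionReport(df, min(pcts), max(pcts))


def load_published_polyporales_summary() -> pd.DataFrame:
    """The transcribed published per-sample filtering outcomes for the five
    Polyporales species (19 rows).

    Ranged cells (different-strain samples) are kept as strings; the
    ``single_valued`` column marks rows whose cells are all plain counts.
    """
    ref = resources.files("editcheck.data") / "polyporales_reported_sites.tsv"
    with resources.as_file(ref) as path:
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    for col in ("n_reported", "n_dna_match"):
        df[col] = df[col].astype(int)
    df["single_valued"] = ~(
        df["n_pooled_match"].str.contains("-") | df["n_retained"].str.contains("-")
    )
    for col in ("n_absent_realignment",):
        df[col] = df[col].astype(int)
    return df
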