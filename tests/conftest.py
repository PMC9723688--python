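from typing import NamedTuple

import pytest
from hypothesis import HealthCheck, settings

import editcheck as ec

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def default_sim() -> ec.SimResult:
    """The default study conditions: 2 collapsed paralog pairs (5 kb,
    1% divergence), 60x per-copy depths, 100 bp reads, 0.5% base error,
    20 edit sites at rate 0.3, 5 strain SNPs, seed 1."""
    return ec.run_simulation(ec.SimConfig())


@pytest.fixture(scope="session")
def withheld_sim() -> ec.SimResult:
    """Same conditions but error-free, without strain SNPs, and with the
    first pair's DNA alignments withheld (kept in the raw pool) — the
    scenario the pooled-read search exists for.  Strain mode is off
    because an isolate difference adjacent to a paralog-divergent site
    legitimately defeats full-length exact matching."""
    return ec.run_simulation(
        ec.SimConfig(error_rate=0.0, n_strain_snps=0, withhold_dna_alignment_for=(0,))
    )


class ClassifiedSim(NamedTuple):
    calls: list
    verdicts: list
    dna_pileup: ec.Pileup


def classify_sim(sim: ec.SimResult) -> ClassifiedSim:
    """Pileups -> candidates -> verdicts for a simulation, with the raw
    gDNA reads (post-QC) as the pool."""
    thresholds = ec.CallerThresholds()
    rna_pileup = ec.build_pileup(sim.rna_alignments, sim.collapsed_reference, thresholds,
                                 "sim", "RNA")
    dna_pileup = ec.build_pileup(sim.gdna_alignments, sim.collapsed_reference, thresholds,
                                 "sim", "DNA")
    calls = ec.call_candidates(rna_pileup, sim.collapsed_reference, thresholds)
    pool, _ = ec.run_qc(sim.gdna_reads)
    verdicts = ec.classify_sites(
        calls, dna_pileup, gdna_pool=pool, rna_alignments=sim.rna_alignments.reads,
        thresholds=thresholds,
    )
    return ClassifiedSim(calls, verdicts, dna_pileup)


@pytest.fixture(scope="session")
def default_verdicts(default_sim):
    return classify_sim(default_sim)


@pytest.fixture(scope="session")
def withheld_verdicts(withheld_sim):
    return classify_sim(withheld_sim)


def truth_index(sim: ec.SimResult) -> dict[tuple[str, int, str], str]:
    return {(t.site.contig, t.site.pos, t.alt_base): t.truth_class for t in sim.truth}
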