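import math

import numpy as np
import pytest

import editcheck as ec
from editcheck.simulate import COLLAPSED_CONTIG, Simulator


SMALL = dict(
    genome_length=2200, n_paralog_pairs=1, segment_length=600, read_length=50,
    n_edit_sites=4, n_strain_snps=2, dna_depth=30, rna_depth=30,
)


class TestGenerateGenome:
    def test_no_engineered_sites_no_truth(self):
        cfg = ec.SimConfig(**{**SMALL, "divergence": 0.0, "n_edit_sites": 0, "n_strain_snps": 0})
        _, _, truth = ec.generate_genome(cfg)
        assert truth == []

    def test_collapsed_reference_is_copy1_only(self):
        cfg = ec.SimConfig(**SMALL)
        true_genome, collapsed, _ = ec.generate_genome(cfg)
        assert list(collapsed.contigs) == [COLLAPSED_CONTIG]
        assert true_genome.contigs[COLLAPSED_CONTIG] == collapsed.contigs[COLLAPSED_CONTIG]
        assert "dup1" in true_genome.contigs

    def test_copy2_differs_exactly_at_artifact_sites(self):
        cfg = ec.SimConfig(**SMALL)
        true_genome, collapsed, truth = ec.generate_genome(cfg)
        s = cfg.segment_start(0)
        copy1 = collapsed.contigs[COLLAPSED_CONTIG][s : s + cfg.segment_length]
        copy2 = true_genome.contigs["dup1"]
        diffs = {i for i, (a, b) in enumerate(zip(copy1, copy2)) if a != b}
        artifacts = {
            t.site.pos - s for t in truth if t.truth_class == ec.PARALOG_ARTIFACT
        }
        assert diffs == artifacts
        for t in truth:
            if t.truth_class == ec.PARALOG_ARTIFACT:
                assert copy2[t.site.pos - s] == t.alt_base

    def test_truth_classes_never_collide(self):
        _, _, truth = ec.generate_genome(ec.SimConfig())
        sites = [t.site for t in truth]
        assert len(sites) == len(set(sites))

    def test_edit_sites_on_adenosine(self):
        _, collapsed, truth = ec.generate_genome(ec.SimConfig(**SMALL))
        for t in truth:
            if t.truth_class == ec.TRUE_EDIT:
                assert (t.ref_base, t.alt_base) == ("A", "G")
                assert collapsed.base(t.site.contig, t.site.pos) == "A"

    def test_infeasible_config_rejected(self):
        cfg = dict(SMALL)
        cfg["n_edit_sites"] = 10_000
        with pytest.raises(ValueError, match="infeasible"):
            ec.generate_genome(ec.SimConfig(**cfg))

    def test_divergence_count_matches_binomial_expectation(self):
        """Across 100 seeds, the mean artifact count tracks the Binomial
        mean n*p within 3 sigma of the mean estimator."""
        n, p = 5000, 0.01
        counts = []
        for seed in range(100):
            cfg = ec.SimConfig(
                genome_length=5300, n_paralog_pairs=1, segment_length=n,
                divergence=p, n_edit_sites=0, n_strain_snps=0, seed=seed,
            )
            _, _, truth = ec.generate_genome(cfg)
            counts.append(len(truth))
        mean = float(np.mean(counts))
        sigma_mean = math.sqrt(n * p * (1 - p)) / math.sqrt(len(counts))
        assert abs(mean - n * p) <= 3 * sigma_mean


class TestSimulateReads:
    def test_same_seed_byte_identical(self):
        a = ec.run_simulation(ec.SimConfig(**SMALL))
        b = ec.run_simulation(ec.SimConfig(**SMALL))
        assert [(r.read_id, r.sequence, r.qualities) for r in a.gdna_reads] == [
            (r.read_id, r.sequence, r.qualities) for r in b.gdna_reads
        ]
        assert [(r.read_id, r.start, r.cigar, r.sequence, r.flags) for r in a.rna_alignments] == [
            (r.read_id, r.start, r.cigar, r.sequence, r.flags) for r in b.rna_alignments
        ]
        assert a.truth == b.truth

    def test_mean_coverage_within_twenty_percent(self):
        cfg = ec.SimConfig(**{**SMALL, "error_rate": 0.0})
        sim = ec.run_simulation(cfg)
        genome_size = sum(len(s) for s in sim.true_genome.contigs.values())
        mean_cov = sum(len(r.sequence) for r in sim.gdna_reads) / genome_size
        assert abs(mean_cov - cfg.dna_depth) / cfg.dna_depth <= 0.20

    def test_edit_rate_one_every_molecule_edited(self):
        cfg = ec.SimConfig(**{**SMALL, "edit_rate": 1.0, "error_rate": 0.0})
        sim = ec.run_simulation(cfg)
        edits = [t for t in sim.truth if t.truth_class == ec.TRUE_EDIT]
        assert edits
        for t in edits:
            for read in sim.rna_alignments:
                hit = read.base_at(t.site.pos)
                if hit is not None:
                    assert hit[0] == "G"

    def test_edit_rate_zero_no_alt(self):
        cfg = ec.SimConfig(**{**SMALL, "edit_rate": 0.0, "error_rate": 0.0})
        sim = ec.run_simulation(cfg)
        for t in sim.truth:
            if t.truth_class != ec.TRUE_EDIT:
                continue
            for read in sim.rna_alignments:
                hit = read.base_at(t.site.pos)
                if hit is not None:
                    assert hit[0] == "A"

    def test_error_free_dna_reads_match_genome(self):
        cfg = ec.SimConfig(**{**SMALL, "error_rate": 0.0})
        sim = Simulator(cfg)
        sim.run()
        for p in sim.placed_dna[:200]:
            tpl = sim.true_genome.contigs[p.contig]
            assert p.forward_sequence == tpl[p.start : p.start + cfg.read_length]


class TestPlaceAlignments:
    def test_copy2_reads_placed_at_copy1_coordinates(self):
        cfg = ec.SimConfig(**{**SMALL, "error_rate": 0.0})
        sim = Simulator(cfg)
        sim.run()
        s = cfg.segment_start(0)
        dup_aligned = {
            a.read_id: a for a in sim.gdna_alignments if s <= a.start < s + cfg.segment_length
        }
        placed = {p.record.read_id: p for p in sim.placed_dna if p.contig == "dup1"}
        assert placed
        for rid, p in placed.items():
            assert dup_aligned[rid].start == s + p.start

    def test_divergent_base_appears_as_mismatch(self, withheld_sim):
        """A copy-2 read over a divergent site carries the alternative base
        at the collapsed coordinate."""
        truth = withheld_sim.truth_by_class(ec.PARALOG_ARTIFACT)
        t = truth[len(truth) // 2]
        mismatched = 0
        for a in withheld_sim.rna_alignments:
            hit = a.base_at(t.site.pos)
            if hit is not None and hit[0] == t.alt_base:
                mismatched += 1
        assert mismatched > 0

    def test_withheld_pair_absent_from_dna_sam_but_pooled(self, withheld_sim):
        cfg = withheld_sim.config
        lo = cfg.segment_start(0)
        hi = lo + cfg.segment_length
        over = [a for a in withheld_sim.gdna_alignments if a.start < hi and a.end > lo]
        assert over == []
        # the pool keeps every simulated gDNA read
        full = ec.run_simulation(ec.SimConfig(error_rate=0.0, n_strain_snps=0))
        assert len(withheld_sim.gdna_reads) == len(full.gdna_reads)

    def test_spliced_reads_carry_intron_skip(self):
        cfg = ec.SimConfig(**{**SMALL, "include_intron": True, "intron_length": 120})
        sim = Simulator(cfg)
        sim.run()
        spliced = [a for a in sim.rna_alignments if any(op == "N" for _, op in a.cigar)]
        assert spliced
        for a in spliced:
            ops = [op for _, op in a.cigar]
            assert ops == ["M", "N", "M"]
            assert dict((op, n) for n, op in a.cigar)["N"] == 120

    def test_expected_artifact_fraction_near_half(self, default_sim):
        """RNA reads from both copies stack on the collapsed locus, so the
        variant fraction at interior divergent sites is ~0.5."""
        pileup = ec.build_pileup(default_sim.rna_alignments, default_sim.collapsed_reference)
        cfg = default_sim.config
        fracs = []
        for t in default_sim.truth_by_class(ec.PARALOG_ARTIFACT):
            off = (t.site.pos - cfg.segment_start(0)) % (
                cfg.segment_length + cfg.spacer_length
            )
            if not (cfg.read_length < off < cfg.segment_length - cfg.read_length):
                continue
            sf = ec.site_fraction(pileup, t.site, t.alt_base)
            if sf.covered:
                fracs.append(sf.frac)
        assert fracs and abs(float(np.mean(fracs)) - 0.5) < 0.05


class TestTruthTable:
    def test_round_trip_and_sorting(self, tmp_path):
        _, _, truth = ec.generate_genome(ec.SimConfig(**SMALL))
        path = tmp_path / "truth.tsv"
        ec.write_truth(truth, path)
        df = ec.read_truth(path)
        assert len(df) == len(truth)
        assert list(df["pos"]) == sorted(df["pos"])
        by_site = {(t.site.contig, t.site.pos): t for t in truth}
        for _, row in df.iterrows():
            t = by_site[(row["contig"], row["pos"])]
            assert (row["truth_class"], row["ref"], row["alt"]) == (
                t.truth_class, t.ref_base, t.alt_base,
            )

    def test_empty_truth_header_only(self, tmp_path):
        path = tmp_path / "truth.tsv"
        ec.write_truth([], path)
        assert path.read_text().splitlines() == [
            "contig\tpos\ttruth_class\tref\talt\texpected_alt_frac"
        ]

    def test_fixture_files_written(self, tmp_path):
        out = tmp_path / "fx"
        ec.run_simulation(ec.SimConfig(**SMALL), outdir=out)
        for name in (
            "true_genome.fa", "collapsed_ref.fa", "gdna.fastq", "rna.fastq",
            "gdna.sam", "rna.sam", "truth.tsv", "config.json",
        ):
            assert (out / name).exists()
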