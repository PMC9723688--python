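import numpy as np
import pytest

import editcheck as ec
from editcheck.filters import PooledReadIndex
from conftest import truth_index
from oracles import naive_containment_scan
from test_pileup_caller import pileup_from_counts

REF = ec.ReferenceGenome({"c1": "A" * 200})
TH = ec.CallerThresholds()


def call(pos=10, ref="A", alt="G", depth=50, alt_count=25):
    return ec.VariantCall(ec.SiteKey("c1", pos), ref, alt, depth, alt_count)


def dna_pileup(counts_by_pos):
    return pileup_from_counts(REF, counts_by_pos)


class TestDnaMatchFilter:
    def test_matching_substitution_above_five_percent_removed(self):
        matched, passed = ec.filter_dna_match([call()], dna_pileup({10: {"A": 80, "G": 20}}), TH)
        assert len(matched) == 1 and not passed
        assert matched[0].category == ec.DNA_MATCH
        assert matched[0].evidence["dna_frac"] == 0.2

    def test_four_percent_not_matched(self):
        matched, passed = ec.filter_dna_match([call()], dna_pileup({10: {"A": 96, "G": 4}}), TH)
        assert not matched and len(passed) == 1

    def test_exactly_five_percent_not_matched(self):
        # the presence threshold is strictly greater-than
        matched, _ = ec.filter_dna_match([call()], dna_pileup({10: {"A": 95, "G": 5}}), TH)
        assert not matched

    def test_different_substitution_type_not_matched(self):
        matched, passed = ec.filter_dna_match([call()], dna_pileup({10: {"A": 80, "C": 20}}), TH)
        assert not matched and len(passed) == 1

    def test_zero_dna_coverage_passes_onward(self):
        matched, passed = ec.filter_dna_match([call()], dna_pileup({}), TH)
        assert not matched and len(passed) == 1


class TestRealignmentFilter:
    def test_zero_depth_in_second_pileup_is_absent(self):
        absent, _ = ec.filter_absent_in_realignment([call()], dna_pileup({}), TH)
        assert absent[0].category == ec.ABSENT_IN_REALIGNMENT

    def test_identical_support_passes(self):
        second = dna_pileup({10: {"A": 25, "G": 25}})
        absent, passed = ec.filter_absent_in_realignment([call()], second, TH)
        assert not absent and len(passed) == 1

    def test_subthreshold_alt_count_is_absent(self):
        second = dna_pileup({10: {"A": 22, "G": 3}})
        absent, _ = ec.filter_absent_in_realignment([call()], second, TH)
        assert len(absent) == 1

    def test_missing_second_pileup_skips_filter(self):
        absent, passed = ec.filter_absent_in_realignment([call()], None, TH)
        assert not absent and len(passed) == 1


def _rna_read(seq, start, rid="rna1"):
    return ec.AlignedRead(rid, "c1", start, [(len(seq), "M")], seq)


def _pool(*seqs):
    return [ec.ReadRecord(f"g{i}", s) for i, s in enumerate(seqs)]


class TestPooledSearch:
    params = ec.PooledSearchParams(kmer_size=11)

    def setup_method(self):
        rng = np.random.default_rng(99)
        self.rna_seq = "".join("ACGT"[i] for i in rng.integers(0, 4, size=40))
        # variant-supporting read: alt G at query offset 20, ref pos 30
        self.rna_seq = self.rna_seq[:20] + "G" + self.rna_seq[21:]
        self.read = _rna_read(self.rna_seq, start=10)
        self.call = ec.VariantCall(ec.SiteKey("c1", 30), "A", "G", 50, 25)

    def search(self, pool, params=None):
        return ec.pooled_genomic_search(
            [self.call], [self.read], pool, params or self.params
        )

    def test_verbatim_containment_matches(self):
        pool = _pool("TTTT" + self.rna_seq + "CCCC")
        matched, passed = self.search(pool)
        assert matched and not passed
        assert matched[0].evidence["n_pool_reads"] == 1

    def test_reverse_complement_matches(self):
        pool = _pool(ec.revcomp("TT" + self.rna_seq))
        matched, _ = self.search(pool)
        assert matched

    def test_revcomp_search_can_be_disabled(self):
        pool = _pool(ec.revcomp("TT" + self.rna_seq))
        params = ec.PooledSearchParams(kmer_size=11, search_revcomp=False)
        matched, passed = self.search(pool, params)
        assert not matched and passed

    def test_single_mismatch_not_matched(self):
        mutated = self.rna_seq[:5] + ("A" if self.rna_seq[5] != "A" else "C") + self.rna_seq[6:]
        matched, passed = self.search(_pool("TT" + mutated + "AA"))
        assert not matched and passed

    def test_shorter_pool_read_must_cover_variant(self):
        # pool read equals a query fragment NOT covering offset 20 -> no match
        matched, _ = self.search(_pool(self.rna_seq[:18]))
        assert not matched
        # ... and one covering it -> match
        matched, _ = self.search(_pool(self.rna_seq[12:32]))
        assert matched

    def test_min_hits_respected(self):
        pool = _pool("TT" + self.rna_seq)
        params = ec.PooledSearchParams(kmer_size=11, min_hits=2)
        matched, passed = self.search(pool, params)
        assert not matched and passed

    def test_empty_pool_skips_filter(self):
        matched, passed = self.search([])
        assert not matched and len(passed) == 1

    @pytest.mark.parametrize("case_seed", range(20))
    def test_index_agrees_with_naive_scan(self, case_seed):
        """k-mer-indexed containment equals the brute-force O(pool x read)
        scan, including planted exact containments and near-misses."""
        rng = np.random.default_rng(40_000 + case_seed)
        pool_seqs = [
            "".join("ACGT"[i] for i in rng.integers(0, 4, size=int(rng.integers(8, 60))))
            for _ in range(int(rng.integers(50, 300)))
        ]
        queries = [
            "".join("ACGT"[i] for i in rng.integers(0, 4, size=int(rng.integers(8, 45))))
            for _ in range(5)
        ]
        # plant exact forward/revcomp containments and 1-mismatch decoys
        q = queries[0]
        pool_seqs.append("AC" + q + "GT")
        pool_seqs.append(ec.revcomp(q))
        if len(q) > 4:
            decoy = q[:2] + ("A" if q[2] != "A" else "C") + q[3:]
            pool_seqs.append(decoy)
        queries.append(pool_seqs[0] + "ACGT")  # pool read inside query
        pool = _pool(*pool_seqs)
        params = ec.PooledSearchParams(kmer_size=11)
        index = PooledReadIndex(pool, params)
        for query in queries:
            got = {(c.pool_read_id, c.q_start, c.q_end) for c in index.containments(query)}
            assert got == naive_containment_scan(query, pool)


class TestClassify:
    def test_precedence_dna_match_wins(self):
        c = call()
        dna = dna_pileup({10: {"A": 80, "G": 20}})
        read = _rna_read("G" * 40, start=0)
        pool = _pool("G" * 60)
        verdicts = ec.classify_sites(
            [c], dna, gdna_pool=pool, rna_alignments=[read], thresholds=TH,
            pooled_params=ec.PooledSearchParams(kmer_size=11),
        )
        assert verdicts[0].category == ec.DNA_MATCH

    def test_no_optional_inputs_everything_not_matched_is_retained(self):
        verdicts = ec.classify_sites([call()], dna_pileup({}), thresholds=TH)
        assert verdicts[0].category == ec.RETAINED

    def test_conservation_partition(self, default_verdicts):
        calls, verdicts, _ = default_verdicts
        by_cat: dict[str, int] = {}
        for v in verdicts:
            by_cat[v.category] = by_cat.get(v.category, 0) + 1
        assert sum(by_cat.values()) == len(calls)
        assert len(verdicts) == len(calls)

    def test_simulated_artifacts_all_explained(self, default_verdicts, default_sim):
        """Artifact candidates with adequate DNA coverage are genomically
        matched; genuine edits and strain SNPs survive."""
        calls, verdicts, _ = default_verdicts
        truth = truth_index(default_sim)
        artifact = [v for v in verdicts if truth.get(v.call.key) == ec.PARALOG_ARTIFACT]
        assert artifact
        assert all(v.category == ec.DNA_MATCH for v in artifact)
        edits = [v for v in verdicts if truth.get(v.call.key) == ec.TRUE_EDIT]
        assert sum(v.category == ec.RETAINED for v in edits) / len(edits) >= 0.95

    def test_withheld_dna_rescued_by_pool(self, withheld_verdicts, withheld_sim):
        """With DNA alignments withheld for one pair, its artifact
        candidates are explained by the pooled raw-read search instead."""
        calls, verdicts, _ = withheld_verdicts
        truth = truth_index(withheld_sim)
        cfg = withheld_sim.config
        lo = cfg.segment_start(0)
        hi = lo + cfg.segment_length
        withheld = [
            v
            for v in verdicts
            if truth.get(v.call.key) == ec.PARALOG_ARTIFACT and lo <= v.call.site.pos < hi
        ]
        assert withheld
        assert all(v.category == ec.POOLED_GENOMIC_MATCH for v in withheld)
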