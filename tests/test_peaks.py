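"""Differential eccDNA activity: counting, normalisation, Fisher test,
multiple-testing correction and status rules."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mobilome.align import AlignmentRecord
from mobilome.catalog import TEElement
from mobilome.peaks import (call_differential, count_reads_per_element,
                            normalize_cpm100k)
from oracles import count_overlaps, fisher_two_sided


def _rec(rid, chrom, s, e, primary=True):
    return AlignmentRecord(
        query_id=rid, query_start=0, query_end=e - s, target_id=chrom,
        target_start=s, target_end=e, strand="+", matches=e - s,
        aln_columns=e - s, cigar=[("=", e - s)], score=e - s,
        is_primary=primary, query_len=e - s, target_len=10_000_000)


def _elem(eid, chrom, s, e):
    return TEElement(eid, chrom, s, e)


class TestCounting:
    ANN = [_elem("A", "c1", 1_000, 6_000), _elem("B", "c1", 8_000, 13_000),
           _elem("C", "c2", 2_000, 7_000)]

    def test_reads_inside_one_element(self):
        recs = [_rec(f"r{i}", "c1", 2_000, 4_500) for i in range(10)]
        counts, un = count_reads_per_element(recs, self.ANN)
        assert counts == {"A": 10, "B": 0, "C": 0}
        assert un == 0

    def test_largest_overlap_wins(self):
        # overlaps A by 300 bp and B by 150 bp via a gap-spanning interval
        ann = [_elem("A", "c1", 1_000, 2_000), _elem("B", "c1", 2_150, 3_000)]
        recs = [_rec("r0", "c1", 1_700, 2_300)]
        counts, _ = count_reads_per_element(recs, ann)
        assert counts == {"A": 1, "B": 0}

    def test_min_overlap_filter(self):
        recs = [_rec("r0", "c1", 950, 1_050)]  # 50 bp overlap with A
        counts, un = count_reads_per_element(recs, self.ANN, min_overlap=100)
        assert sum(counts.values()) == 0
        assert un == 1

    def test_unknown_chromosome_raises(self):
        with pytest.raises(ValueError, match="unknown chromosome"):
            count_reads_per_element([_rec("r0", "cX", 0, 500)], self.ANN)

    def test_secondary_alignments_ignored(self):
        recs = [_rec("r0", "c1", 2_000, 3_000),
                _rec("r0", "c1", 9_000, 10_000, primary=False)]
        counts, _ = count_reads_per_element(recs, self.ANN)
        assert counts["A"] == 1 and counts["B"] == 0

    def test_matches_naive_oracle_on_random_placement(self):
        """1,000 random read placements against a brute-force O(n*m)
        largest-overlap oracle: counts agree exactly (and conserve)."""
        rng = np.random.default_rng(43)
        ann = []
        pos = 0
        for i in range(30):
            pos += int(rng.integers(2_000, 9_000))
            ann.append(_elem(f"e{i}", "c1", pos, pos + int(rng.integers(
                1_000, 6_000))))
            pos = ann[-1].end
        recs, ivals = [], []
        for i in range(1_000):
            s = int(rng.integers(0, pos))
            e = s + int(rng.integers(200, 5_000))
            recs.append(_rec(f"r{i}", "c1", s, e))
            ivals.append(("c1", s, e))
        counts, un = count_reads_per_element(recs, ann, min_overlap=100)
        exp_counts, exp_un = count_overlaps(
            ivals, [(a.id, a.chrom, a.start, a.end) for a in ann], 100)
        assert counts == exp_counts
        assert un == exp_un
        assert sum(counts.values()) + un == 1_000  # conservation


class TestNormalize:
    def test_paper_scale_example(self):
        assert normalize_cpm100k(32, 64_000) == 50.0

    def test_zero_count(self):
        assert normalize_cpm100k(0, 48_000) == 0.0

    def test_full_library(self):
        assert normalize_cpm100k(64_000, 64_000) == 100_000.0

    def test_empty_library_raises(self):
        with pytest.raises(ValueError, match="empty library"):
            normalize_cpm100k(1, 0)


class TestDifferential:
    def test_symmetric_table_p_one(self):
        recs = call_differential({"e": 5}, {"e": 5}, (1_000, 1_000))
        assert recs[0].p_value == pytest.approx(1.0)
        assert recs[0].status == "low_count"  # 10 reads, needs > 10

    def test_p_matches_hypergeometric_oracle(self):
        """Fisher p equals an exact big-integer hypergeometric summation
        to 1e-10 on random 2x2 tables."""
        rng = np.random.default_rng(47)
        for _ in range(50):
            a, b = int(rng.integers(0, 40)), int(rng.integers(0, 40))
            nt, nc = int(rng.integers(100, 2_000)), int(rng.integers(
                100, 2_000))
            rec = call_differential({"e": a}, {"e": b}, (nt, nc),
                                    min_reads=0)[0]
            assert rec.p_value == pytest.approx(
                fisher_two_sided(a, nt - a, b, nc - b), abs=1e-10)

    def test_paper_threshold_rules(self):
        """An element with 11 supporting reads, adjusted p below 0.01 and
        treatment enrichment is significant; a depleted one is not."""
        recs = call_differential({"up": 11, "down": 0},
                                 {"up": 0, "down": 11}, (5_000, 5_000),
                                 min_reads=10, alpha=0.01)
        by_id = {r.element_id: r for r in recs}
        assert by_id["up"].status == "significant"
        assert by_id["up"].p_adj < 0.01
        assert by_id["down"].status == "tested"  # enriched in control only

    def test_low_count_excluded_from_testing(self):
        recs = call_differential({"a": 3, "b": 50}, {"a": 0, "b": 2},
                                 (1_000, 1_000))
        by_id = {r.element_id: r for r in recs}
        assert by_id["a"].status == "low_count"
        assert by_id["b"].status == "significant"

    def test_invalid_counts_raise(self):
        with pytest.raises(ValueError):
            call_differential({"e": -1}, {"e": 0}, (10, 10))
        with pytest.raises(ValueError):
            call_differential({"e": 20}, {"e": 0}, (10, 10))
        with pytest.raises(ValueError, match="empty library"):
            call_differential({"e": 1}, {"e": 0}, (10, 0))

    def test_output_sorted_by_p_adj(self):
        rng = np.random.default_rng(53)
        ct = {f"e{i}": int(rng.integers(0, 60)) for i in range(20)}
        cc = {f"e{i}": int(rng.integers(0, 60)) for i in range(20)}
        recs = call_differential(ct, cc, (3_000, 3_000))
        keys = [(r.p_adj, r.element_id) for r in recs]
        assert keys == sorted(keys)

    @settings(max_examples=20, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_bh_adjustment_properties(self, seed):
        """p_adj >= p, p_adj <= 1, and BH is monotone in the p ordering."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 25))
        ct = {f"e{i}": int(rng.integers(0, 80)) for i in range(n)}
        cc = {f"e{i}": int(rng.integers(0, 80)) for i in range(n)}
        recs = call_differential(ct, cc, (2_000, 2_000), min_reads=0)
        tested = sorted(recs, key=lambda r: r.p_value)
        for r in recs:
            assert r.p_adj >= r.p_value - 1e-12
            assert r.p_adj <= 1.0
        adjs = [r.p_adj for r in tested]
        assert adjs == sorted(adjs)

    def test_bonferroni_option(self):
        recs = call_differential({"a": 30, "b": 1}, {"a": 1, "b": 1},
                                 (1_000, 1_000), min_reads=0,
                                 correction="bonferroni")
        by_id = {r.element_id: r for r in recs}
        assert by_id["a"].p_adj == pytest.approx(
            min(1.0, by_id["a"].p_value * 2))
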