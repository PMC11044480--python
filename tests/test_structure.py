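"""Concatemer decomposition, circle-structure classification, divergence
pileup, and origin assignment."""

import numpy as np
import pytest

from conftest import mutate, noisy_copy, random_seq
from mobilome.catalog import TEElement
from mobilome.structure import (assign_origin, classify_structure,
                                consensus_divergence, decompose_concatemer)

RNG = np.random.default_rng(61)
LTR = random_seq(RNG, 500)
INTERNAL = random_seq(RNG, 3_000)
ELEMENT = LTR + INTERNAL + LTR
ELEM = TEElement("el", "c1", 0, len(ELEMENT), ltr5=(0, 500),
                 ltr3=(3_500, 4_000))


def tandem_read(circle: str, copies: float, phase: int) -> str:
    n = int(len(circle) * copies)
    reps = -(-(phase + n) // len(circle))
    return (circle * reps)[phase:phase + n]


class TestDecompose:
    def test_error_free_all_phases_exact(self):
        """Monomer length equals the circle length exactly for every
        rotation phase of an error-free concatemer."""
        circle = LTR + INTERNAL[:700]  # 1.2 kb circle
        for phase in range(0, len(circle), 120):
            read = tandem_read(circle, 3.4, phase)
            d = decompose_concatemer(read, ELEMENT)
            assert d.monomer_len == len(circle)
            assert d.n_full_monomers == 3

    def test_noisy_monomer_length_within_2pct(self):
        rng = np.random.default_rng(67)
        circle = LTR + INTERNAL[:1_000]
        for _ in range(15):
            read = noisy_copy(tandem_read(circle, 3.2,
                                          int(rng.integers(len(circle)))),
                              rng)
            d = decompose_concatemer(read, ELEMENT)
            assert abs(d.monomer_len - len(circle)) / len(circle) <= 0.02

    def test_no_hit_returns_empty_not_error(self):
        other = random_seq(np.random.default_rng(3), 2_000)
        d = decompose_concatemer(other, ELEMENT)
        assert d.empty
        assert d.n_full_monomers == 0

    def test_empty_element_raises(self):
        with pytest.raises(ValueError):
            decompose_concatemer("ACGT" * 100, "")

    def test_short_read_raises(self):
        with pytest.raises(ValueError):
            decompose_concatemer("ACGT" * 20, ELEMENT)

    def test_few_monomers_no_consensus(self):
        circle = LTR + INTERNAL
        read = tandem_read(circle, 1.5, 0)  # <2 full monomers
        d = decompose_concatemer(read, ELEMENT)
        assert d.n_full_monomers <= 1
        assert d.consensus == ""

    def test_consensus_length_tracks_monomer(self):
        circle = LTR + INTERNAL[:800]
        read = tandem_read(circle, 4.3, 321)
        d = decompose_concatemer(read, ELEMENT)
        assert d.consensus
        assert abs(len(d.consensus) - d.monomer_len) <= 0.1 * d.monomer_len

    def test_junctions_supported_on_contiguous_concatemer(self):
        circle = LTR + INTERNAL[:900]
        d = decompose_concatemer(tandem_read(circle, 3.6, 50), ELEMENT)
        assert d.n_full_monomers >= 3
        assert all(d.junction_supported)


class TestClassify:
    CASES = [
        ("solo_LTR", lambda: LTR),
        ("full_1LTR", lambda: LTR + INTERNAL),
        ("full_2LTR", lambda: ELEMENT),
        ("truncated", lambda: INTERNAL[400:2_000]),
    ]

    @pytest.mark.parametrize("expected,circle_fn",
                             CASES, ids=[c[0] for c in CASES])
    def test_rule_branches(self, expected, circle_fn):
        circle = circle_fn()
        for phase in (0, len(circle) // 3, 2 * len(circle) // 3):
            read = tandem_read(circle, 3.5, phase)
            d = decompose_concatemer(read, ELEMENT)
            call = classify_structure(d, ELEM)
            assert call.structure_class == expected, (expected, phase)

    def test_classification_with_read_errors(self):
        rng = np.random.default_rng(71)
        ok = tot = 0
        for expected, circle_fn in self.CASES:
            circle = circle_fn()
            for _ in range(5):
                read = noisy_copy(
                    tandem_read(circle, 3.2, int(rng.integers(len(circle)))),
                    rng)
                d = decompose_concatemer(read, ELEMENT)
                tot += 1
                ok += classify_structure(d, ELEM).structure_class == expected
        assert ok / tot >= 0.9

    def test_planted_deletion_reported(self):
        """A 25 bp internal deletion in the circle is reported as one
        deletion interval of length 25."""
        circle = LTR + INTERNAL[:1_200] + INTERNAL[1_225:]
        read = tandem_read(circle, 3.0, 0)
        d = decompose_concatemer(read, ELEMENT)
        call = classify_structure(d, ELEM)
        dels = [(s, e) for s, e in call.deletions]
        assert any(e - s == 25 and abs(s - (500 + 1_200)) <= 3
                   for s, e in dels)

    def test_missing_ltr_annotation_raises(self):
        bare = TEElement("x", "c1", 0, len(ELEMENT))
        d = decompose_concatemer(tandem_read(LTR, 4.0, 0), ELEMENT)
        with pytest.raises(ValueError):
            classify_structure(d, bare)


class TestDivergence:
    def _decomps(self, circle, n_reads, rng, rates=(0.0, 0.0, 0.0)):
        out = []
        for i in range(n_reads):
            read = tandem_read(circle, 2.6, int(rng.integers(len(circle))))
            if sum(rates):
                read = noisy_copy(read, rng, rates)
            d = decompose_concatemer(read, ELEMENT, read_id=f"r{i}")
            if not d.empty:
                out.append(d)
        return out

    def test_planted_snps_called_exactly_error_free(self):
        rng = np.random.default_rng(73)
        # divergence planted in the internal region (a site inside one
        # LTR is diluted by the other, identical LTR during pileup)
        mid, pos0 = mutate(INTERNAL[20:-20], 20, rng)
        mutated = LTR + INTERNAL[:20] + mid + INTERNAL[-20:] + LTR
        pos = sorted(520 + q for q in pos0)
        decomps = self._decomps(mutated, 12, rng)
        rep = consensus_divergence(decomps, ELEM, ELEMENT)
        assert rep.snp_count == 20
        assert rep.snp_positions == pos
        assert rep.ltr_covered

    def test_snp_recall_under_read_errors(self):
        rng = np.random.default_rng(79)
        mid, pos0 = mutate(INTERNAL[20:-20], 30, rng)
        mutated = LTR + INTERNAL[:20] + mid + INTERNAL[-20:] + LTR
        pos = sorted(520 + q for q in pos0)
        decomps = self._decomps(mutated, 25, rng, (0.05, 0.025, 0.025))
        rep = consensus_divergence(decomps, ELEM, ELEMENT)
        recall = len(set(rep.snp_positions) & set(pos)) / len(pos)
        false = len(set(rep.snp_positions) - set(pos))
        assert recall >= 0.9
        assert false <= 2

    def test_ltr_uncovered_flag(self):
        """Circles made only of internal sequence leave the LTRs
        uncovered."""
        rng = np.random.default_rng(83)
        decomps = self._decomps(INTERNAL, 10, rng)
        rep = consensus_divergence(decomps, ELEM, ELEMENT)
        assert not rep.ltr_covered
        assert rep.ltr_deletion is None

    def test_ltr_deletion_flag(self):
        """Circles whose LTR lacks a 24 bp block show an LTR deletion of
        that length."""
        rng = np.random.default_rng(89)
        circle = LTR[:100] + LTR[124:] + INTERNAL
        decomps = self._decomps(circle, 12, rng)
        rep = consensus_divergence(decomps, ELEM, ELEMENT)
        assert rep.ltr_deletion is not None
        s, e = rep.ltr_deletion
        assert e - s == 24

    def test_empty_input_empty_report(self):
        rep = consensus_divergence([], ELEM, ELEMENT)
        assert rep.snp_count == 0
        assert not rep.ltr_covered


class TestOrigin:
    def _panel(self, rng, query, divs=(0.02, 0.08, 0.20)):
        panel = {}
        for i, div in enumerate(divs):
            g = random_seq(rng, 6_000)
            planted, _ = mutate(query, max(1, int(div * len(query))), rng)
            panel[f"g{i}"] = {"chr": g[:3_000] + planted + g[3_000:]}
        return panel

    def test_verbatim_query_assigned_at_100(self):
        rng = np.random.default_rng(97)
        query = random_seq(rng, 500)
        panel = {"P": {"c": random_seq(rng, 2_000) + query
                       + random_seq(rng, 2_000)},
                 "Q": {"c": random_seq(rng, 5_000)}}
        call = assign_origin(query, panel)
        assert call.assigned == "P"
        assert call.per_genome["P"][0] == 100.0

    def test_closest_genome_wins(self):
        rng = np.random.default_rng(101)
        query = random_seq(rng, 500)
        call = assign_origin(query, self._panel(rng, query))
        assert call.assigned == "g0"
        assert call.margin >= 1.0

    def test_below_floor_is_ambiguous(self):
        """Best identity short of the 96% floor -> ambiguous."""
        rng = np.random.default_rng(103)
        query = random_seq(rng, 500)
        call = assign_origin(query, self._panel(rng, query,
                                                divs=(0.05, 0.1, 0.2)))
        assert max(v[0] for v in call.per_genome.values()) < 96.0
        assert call.assigned == "ambiguous"

    def test_empty_panel_raises(self):
        with pytest.raises(ValueError):
            assign_origin("ACGT" * 50, {})
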