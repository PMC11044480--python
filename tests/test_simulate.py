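"""Synthetic-data generators: construction guarantees, determinism,
error-model calibration, and truth consistency."""

import edlib
import numpy as np
import pytest

from mobilome.catalog import longest_orf_codons, scan_orfs
from mobilome.simulate import (SimConfig, simulate_eccdna_reads,
                               simulate_panel, simulate_reference,
                               simulate_snp_landscape, simulate_wgs_reads)


class TestReference:
    def test_element_count_and_bounds(self, small_reference):
        cfg, genome, elements, truth = small_reference
        assert len(elements) == cfg.n_families * cfg.copies_per_family
        lo = 2 * cfg.ltr_len[0] + cfg.internal_len[0]
        for e in elements:
            assert e.length >= lo
            assert 0 <= e.start < e.end <= len(genome[e.chrom])
            assert e.sequence(genome) == truth.element_seqs[e.id]

    def test_tsd_flanks_duplicated(self, small_reference):
        cfg, genome, elements, _ = small_reference
        t = cfg.tsd_len
        for e in elements:
            chrom = genome[e.chrom]
            assert chrom[e.start - t:e.start] == chrom[e.end:e.end + t]

    def test_planted_orf_lengths(self, small_reference):
        """Planted reading frames of 1302 (family 1) and 352 + 1173
        codons (family 2) are recovered by the 6-frame scan."""
        _, _, _, truth = small_reference
        assert longest_orf_codons(truth.family_consensus["FAM1"]) == 1302
        lens = sorted(o[3] for o in
                      scan_orfs(truth.family_consensus["FAM2"],
                                min_codons=300))
        assert lens == [352, 1173]

    def test_determinism(self):
        cfg = lambda: SimConfig(seed=7, chrom_lengths=(300_000,))  # noqa
        g1, e1, t1 = simulate_reference(cfg())
        g2, e2, t2 = simulate_reference(cfg())
        assert g1 == g2
        assert [(e.id, e.start, e.end) for e in e1] == \
            [(e.id, e.start, e.end) for e in e2]
        assert t1.element_seqs == t2.element_seqs

    def test_overfull_chromosome_raises(self):
        with pytest.raises(ValueError, match="capacity"):
            simulate_reference(SimConfig(chrom_lengths=(20_000,),
                                         copies_per_family=5))

    def test_family_identity_structure(self, small_reference):
        from mobilome.align import global_identity

        _, genome, elements, truth = small_reference
        fam1 = [e for e in elements if e.family == "FAM1"]
        fam2 = [e for e in elements if e.family == "FAM2"]
        within = global_identity(fam1[0].ltr5_sequence(genome),
                                 fam1[1].ltr5_sequence(genome))
        between = global_identity(fam1[0].ltr5_sequence(genome),
                                  fam2[0].ltr5_sequence(genome))
        assert within >= 90.0
        assert between < 80.0


class TestEccReads:
    def test_read_count_and_truth_classes(self):
        cfg = SimConfig(seed=9, chrom_lengths=(300_000,),
                        reads_per_condition=50,
                        ecc_mix={"treatment": {"full_1LTR": 1.0},
                                 "control": {"full_1LTR": 1.0}})
        _, _, truth = simulate_reference(cfg)
        reads = simulate_eccdna_reads(cfg, truth, "treatment")
        assert len(reads) == 50
        assert all(truth.circle_structures[r]["class"] == "full_1LTR"
                   for r in reads)

    def test_zero_error_read_is_circle_rotation(self):
        cfg = SimConfig(seed=9, chrom_lengths=(300_000,),
                        reads_per_condition=5, error_rates=(0, 0, 0),
                        ecc_mix={"treatment": {"solo_LTR": 1.0},
                                 "control": {"solo_LTR": 1.0}})
        _, _, truth = simulate_reference(cfg)
        reads = simulate_eccdna_reads(cfg, truth, "treatment")
        from mobilome.seq import revcomp

        for rid, seq in reads.items():
            info = truth.circle_structures[rid]
            elem = truth.element_seqs[info["element"]]
            circle = elem[:info["circle_len"]]  # solo LTR = 5' LTR prefix
            doubled = circle * (len(seq) // len(circle) + 2)
            assert seq in doubled or revcomp(seq) in doubled

    def test_error_rate_calibration(self):
        """With (sub, ins, del) = (0.05, 0.025, 0.025) the mean edit
        distance of reads to their error-free templates is ~10% of the
        template length (checked with an independent alignment library)."""
        rng = np.random.default_rng(13)
        from mobilome.seq import decode_seq, encode_seq
        from mobilome.simulate import apply_read_errors

        rates = []
        for _ in range(200):
            n = int(rng.integers(800, 2_000))
            template = "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])
            read = decode_seq(apply_read_errors(
                encode_seq(template), rng, (0.05, 0.025, 0.025)))
            d = edlib.align(read, template, task="distance")["editDistance"]
            rates.append(d / n)
        assert 0.08 <= float(np.mean(rates)) <= 0.12

    def test_enrichment_weights(self):
        cfg = SimConfig(seed=9, chrom_lengths=(600_000,),
                        reads_per_condition=2_000)
        _, _, truth = simulate_reference(cfg)
        reads = simulate_eccdna_reads(cfg, truth, "treatment")
        counts = {}
        for rid in reads:
            e = truth.circle_structures[rid]["element"]
            counts[e] = counts.get(e, 0) + 1
        active = np.mean([counts.get(e, 0) for e in truth.active_elements])
        inactive = np.mean([counts.get(e.id, 0) for e in truth.te_catalog
                            if e.id not in truth.active_elements])
        assert 6.0 < active / inactive < 16.0  # nominal 10x


class TestWgs:
    def test_segment_snp_count_binomial(self):
        """fold=20, background 1e-4/bp, 10 Mb segment: expected segment
        SNP count 20,000 within 3 sigma."""
        rng = np.random.default_rng(41)
        variants, segs = simulate_snp_landscape(
            {"c6": 50_000_000}, 1e-4, ("c6", 2_000_000, 12_000_000, 20.0),
            rng)
        in_seg = sum(1 for _, p in variants if 2_000_000 <= p < 12_000_000)
        expect = 1e-4 * 20 * 10_000_000
        sigma = np.sqrt(expect)
        assert abs(in_seg - expect) < 3 * sigma
        assert segs == [("c6", 2_000_000, 12_000_000)]

    def test_read_count_tracks_depth(self, small_reference):
        cfg, genome, _, truth = small_reference
        cfg2 = SimConfig(seed=cfg.seed, chrom_lengths=cfg.chrom_lengths,
                         wgs_depth=8.0,
                         introgression=cfg.introgression)
        g, e, t = simulate_reference(cfg2)
        reads = simulate_wgs_reads(cfg2, t, g)
        total = sum(len(s) for s in reads.values())
        depth = total / len(g["chr1"])
        assert 0.85 * 8.0 <= depth <= 1.15 * 8.0

    def test_insertion_visible_in_reads(self):
        cfg = SimConfig(seed=19, chrom_lengths=(300_000,), wgs_depth=6.0,
                        error_rates=(0, 0, 0), introgression=None,
                        n_default_insertions=1)
        g, e, t = simulate_reference(cfg)
        reads = simulate_wgs_reads(cfg, t, g)
        site = t.insertion_sites[0]
        elem = t.element_seqs[site["element"]]
        probe = elem[:60]
        from mobilome.seq import revcomp

        assert any(probe in s or probe in revcomp(s)
                   for s in reads.values())

    def test_insertion_inside_element_rejected(self):
        cfg = SimConfig(seed=19, chrom_lengths=(300_000,),
                        introgression=None)
        g, elements, t = simulate_reference(cfg)
        cfg.insertions = [("FAM1", "chr1", elements[0].start + 100, 5)]
        with pytest.raises(ValueError, match="inside annotated element"):
            simulate_wgs_reads(cfg, t, g)


def test_panel_divergence_ordering(small_reference):
    """panel_A carries the least diverged copies of the active elements."""
    from mobilome.align import global_identity

    cfg, _, _, truth = small_reference
    panel = simulate_panel(truth, cfg)
    assert set(panel) == {"panel_A", "panel_B", "panel_C"}
    eid = truth.active_elements[0]
    elem = truth.element_seqs[eid]
    idents = {}
    for name, g in panel.items():
        seq = next(iter(g.values()))
        planted = seq[10_000:10_000 + len(elem)]
        idents[name] = global_identity(elem, planted)
    assert idents["panel_A"] > idents["panel_B"] > idents["panel_C"]
    assert idents["panel_A"] >= 96.0
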