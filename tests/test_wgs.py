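"""WGS analysis: pileup SNP calling, density windows, introgression
segmentation, TE insertion calling, VCF round trip."""

import numpy as np
import pytest

from mobilome.align import ReferenceIndex, map_long_read
from mobilome.simulate import (SimConfig, simulate_reference,
                               simulate_snp_landscape, simulate_wgs_reads)
from mobilome.wgs import (SnpDensityTrack, call_snps_naive, call_teis,
                          read_vcf, segment_introgressions,
                          snp_density_windows, write_vcf)
from oracles import segment_runs


@pytest.fixture(scope="module")
def wgs_scene():
    """Small error-free WGS scenario with mapped reads."""
    cfg = SimConfig(seed=31, chrom_lengths=(400_000,), wgs_depth=12.0,
                    error_rates=(0.0, 0.0, 0.0),
                    introgression=("chr1", 50_000, 150_000, 20.0),
                    n_default_insertions=2)
    genome, elements, truth = simulate_reference(cfg)
    reads = simulate_wgs_reads(cfg, truth, genome)
    index = ReferenceIndex(genome)
    aln = {rid: map_long_read(s, index, query_id=rid)
           for rid, s in reads.items()}
    return cfg, genome, truth, reads, aln


class TestSnpCalling:
    def test_planted_snps_recovered_error_free(self, wgs_scene):
        _, genome, truth, reads, aln = wgs_scene
        flat = [r for rs in aln.values() for r in rs]
        variants = call_snps_naive(flat, reads, genome)
        called = {(v.chrom, v.pos) for v in variants}
        planted = {(c, p) for c, p, _, _ in truth.snps}
        tp = called & planted
        assert len(tp) / len(planted) >= 0.95
        assert len(tp) / max(len(called), 1) >= 0.95
        by_pos = {(v.chrom, v.pos): v for v in variants}
        for key in list(tp)[:20]:
            assert by_pos[key].af == pytest.approx(1.0)

    def test_no_variants_no_calls(self):
        rng = np.random.default_rng(4)
        genome = {"c": "".join(np.array(list("ACGT"))[
            rng.integers(0, 4, 50_000)])}
        index = ReferenceIndex(genome)
        reads = {f"r{i}": genome["c"][i * 3_000:(i * 3_000) + 5_000]
                 for i in range(10)}
        aln = [r for rid, s in reads.items()
               for r in map_long_read(s, index, query_id=rid)]
        assert call_snps_naive(aln, reads, genome) == []

    def test_unknown_chromosome_raises(self, wgs_scene):
        _, genome, _, reads, aln = wgs_scene
        flat = [r for rs in aln.values() for r in rs][:1]
        bad = dict(genome)
        bad.pop("chr1")
        bad["other"] = "ACGT" * 100
        with pytest.raises(ValueError, match="not in reference"):
            call_snps_naive(flat, reads, bad)


class TestDensityWindows:
    def test_simple_density(self):
        variants = [("c", i) for i in range(10)]
        tracks = snp_density_windows(variants, {"c": 1_000_000})
        assert tracks["c"].density.tolist() == [10.0]
        assert tracks["c"].counts.tolist() == [10]

    def test_empty_variants(self):
        tracks = snp_density_windows([], {"c": 3_000_000})
        assert tracks["c"].density.tolist() == [0.0, 0.0, 0.0]
        assert tracks["c"].genome_median == 0.0

    def test_count_conservation_and_partial_window(self):
        rng = np.random.default_rng(9)
        L = 2_500_000
        pos = sorted(int(p) for p in rng.integers(0, L, 500))
        tracks = snp_density_windows([("c", p) for p in pos], {"c": L})
        t = tracks["c"]
        assert t.counts.sum() == 500
        assert len(t.counts) == 3
        # partial last window scaled by its true width (0.5 Mb)
        assert t.density[-1] == pytest.approx(t.counts[-1] / 0.5)

    def test_poisson_uniformity(self):
        """Uniform 1e-4/bp rate: all window densities ~100/Mb within 3
        sigma."""
        rng = np.random.default_rng(15)
        variants, _ = simulate_snp_landscape({"c": 20_000_000}, 1e-4, None,
                                             rng)
        t = snp_density_windows(variants, {"c": 20_000_000})["c"]
        sigma = np.sqrt(100.0)
        assert (np.abs(t.density - 100.0) < 3.5 * sigma).all()

    def test_variant_beyond_chromosome_raises(self):
        with pytest.raises(ValueError, match="beyond"):
            snp_density_windows([("c", 2_000_000)], {"c": 1_000_000})


class TestSegmentation:
    def _track(self, density):
        d = np.asarray(density, dtype=float)
        return SnpDensityTrack("c", 1_000_000, (d / 1.0).astype(int), d,
                               genome_median=float(np.median(d)))

    def test_uniform_density_no_segments(self):
        t = self._track([100.0] * 20)
        assert segment_introgressions(t) == []

    def test_two_segments_not_merged_past_max_gap(self):
        d = [10.0] * 3 + [200.0] * 4 + [10.0] * 5 + [200.0] * 4 + [10.0] * 4
        t = self._track(d)
        segs = segment_introgressions(t, fold_threshold=5, min_windows=3,
                                      max_gap=1)
        assert [(s.start // 10**6, s.end // 10**6) for s in segs] == \
            [(3, 7), (12, 16)]

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(77)
        for _ in range(50):
            n = int(rng.integers(8, 60))
            d = rng.choice([5.0, 40.0, 400.0], n,
                           p=[0.55, 0.25, 0.2]).astype(float)
            t = self._track(list(d))
            if t.genome_median <= 0:
                continue
            got = [(s.start // 10**6, s.end // 10**6)
                   for s in segment_introgressions(t, 5.0, 3, 1)]
            exp = segment_runs(list(d), t.genome_median, 5.0, 3, 1)
            assert got == exp

    def test_order_invariance_of_variant_input(self):
        rng = np.random.default_rng(19)
        variants, _ = simulate_snp_landscape(
            {"c": 30_000_000}, 1e-4, ("c", 5_000_000, 15_000_000, 20.0), rng)
        shuffled = list(variants)
        rng.shuffle(shuffled)
        t1 = snp_density_windows(variants, {"c": 30_000_000})["c"]
        t2 = snp_density_windows(shuffled, {"c": 30_000_000})["c"]
        s1 = segment_introgressions(t1)
        s2 = segment_introgressions(t2)
        assert [(s.start, s.end) for s in s1] == [(s.start, s.end)
                                                 for s in s2]

    def test_zero_median_falls_back_to_absolute(self):
        t = SnpDensityTrack("c", 10**6, np.array([0, 0, 600, 600, 600, 0]),
                            np.array([0.0, 0.0, 600.0, 600.0, 600.0, 0.0]),
                            genome_median=0.0)
        with pytest.warns(UserWarning, match="absolute"):
            segs = segment_introgressions(t)
        assert len(segs) == 1


class TestTeis:
    def test_error_free_exact_recovery(self, wgs_scene):
        cfg, genome, truth, reads, aln = wgs_scene
        lib = dict(truth.family_consensus)
        calls = call_teis(aln, reads, lib, genome, min_support=3)
        planted = {i["position"]: i for i in truth.insertion_sites}
        assert len(calls) == len(planted)  # precision & recall 1.0
        for c in calls:
            assert c.position in planted
            site = planted[c.position]
            assert c.family == site["family"]
            assert c.tsd == site["tsd"]
            assert len(c.tsd) == cfg.tsd_len

    def test_min_support_threshold(self, wgs_scene):
        _, genome, truth, reads, aln = wgs_scene
        calls = call_teis(aln, reads, dict(truth.family_consensus), genome,
                          min_support=10**6)
        assert calls == []

    def test_empty_library_keeps_family_unassigned(self, wgs_scene):
        _, genome, truth, reads, aln = wgs_scene
        calls = call_teis(aln, reads, {}, genome, min_support=3)
        assert all(c.family == "unassigned" for c in calls)


def test_vcf_round_trip(tmp_path, wgs_scene):
    _, genome, _, reads, aln = wgs_scene
    flat = [r for rs in aln.values() for r in rs]
    variants = call_snps_naive(flat, reads, genome)[:50]
    path = tmp_path / "out.vcf"
    write_vcf(variants, {c: len(s) for c, s in genome.items()}, path)
    back = read_vcf(path)
    assert [(v.chrom, v.pos, v.ref, v.alt) for v in back] == \
        [(v.chrom, v.pos, v.ref, v.alt) for v in variants]
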