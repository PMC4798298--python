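"""Bulk segregant mapping: frequency tracks, LOD scan, locus calling."""

import numpy as np
import pytest

from gxemap.bsa import (
    BulkSegregantScan,
    LodTrack,
    call_loci,
    estimate_frequencies,
    lod_scan,
    smooth_track,
    subset_segregating,
)
from gxemap.genome import BY, S3, CrossDesign, GenomeMap
from gxemap.simulate import PoolCounts, simulate_pool_counts
from gxemap.experiments import _class_panel, no_signal_specificity


def line_map(n_snps=49, spacing=800, length=None):
    length = length or (n_snps + 1) * spacing
    pos = np.arange(spacing // 2, spacing // 2 + n_snps * spacing, spacing)
    return GenomeMap((("chrI", length),), np.zeros(n_snps, dtype=int), pos)


class TestSubsetSegregating:
    def make(self, focal):
        gmap = line_map(len(focal))
        design = CrossDesign(gmap, np.array(focal, dtype=np.int8), "BY")
        counts = PoolCounts(np.arange(len(focal)), np.arange(len(focal)) + 1)
        return counts, design

    def test_fully_segregating_is_identity(self):
        counts, design = self.make([S3] * 10)
        sub = subset_segregating(counts, design)
        assert sub.n_sites == 10

    def test_fully_fixed_is_empty(self):
        counts, design = self.make([BY] * 10)
        assert subset_segregating(counts, design).n_sites == 0

    def test_half_fixed_halves_the_sites(self):
        counts, design = self.make([BY] * 5 + [S3] * 5)
        sub = subset_segregating(counts, design)
        assert sub.n_sites == 5
        assert np.array_equal(sub.snp_index, np.arange(5, 10))


class TestFrequencies:
    @pytest.mark.parametrize("cb, cs, f", [(30, 70, 0.7), (50, 50, 0.5)])
    def test_simple_ratio(self, cb, cs, f):
        track = estimate_frequencies(PoolCounts([cb], [cs]))
        assert track.frequency[0] == pytest.approx(f)

    def test_zero_depth_is_missing(self):
        track = estimate_frequencies(PoolCounts([0], [0]))
        assert np.isnan(track.frequency[0])


class TestSmoothing:
    def test_constant_track_is_unchanged(self, gmap):
        n = gmap.n_snps
        from gxemap.bsa import AlleleFrequencyTrack

        track = AlleleFrequencyTrack(np.arange(n), np.full(n, 0.7))
        sm = smooth_track(track, gmap, 25)
        assert np.allclose(sm.frequency, 0.7)

    def test_step_at_window_center(self):
        """0->1 step: the step SNP averages 13 of 25 SNPs at 1 = 0.52."""
        from gxemap.bsa import AlleleFrequencyTrack

        gmap = line_map(49)
        values = np.zeros(49)
        values[24:] = 1.0
        sm = smooth_track(AlleleFrequencyTrack(np.arange(49), values), gmap, 25)
        assert sm.frequency[24] == pytest.approx(13 / 25)

    def test_window_one_is_identity(self, gmap):
        from gxemap.bsa import AlleleFrequencyTrack

        vals = np.linspace(0, 1, gmap.n_snps)
        track = AlleleFrequencyTrack(np.arange(gmap.n_snps), vals)
        assert np.allclose(smooth_track(track, gmap, 1).frequency, vals)

    def test_even_window_rejected(self, gmap):
        from gxemap.bsa import AlleleFrequencyTrack

        track = AlleleFrequencyTrack(np.arange(gmap.n_snps), np.zeros(gmap.n_snps))
        with pytest.raises(ValueError):
            smooth_track(track, gmap, 24)

    def test_missing_values_are_skipped(self):
        from gxemap.bsa import AlleleFrequencyTrack

        gmap = line_map(5)
        vals = np.array([1.0, np.nan, 1.0, 1.0, 1.0])
        sm = smooth_track(AlleleFrequencyTrack(np.arange(5), vals), gmap, 3)
        assert np.allclose(sm.frequency, 1.0, equal_nan=False)


class TestLodScan:
    def test_balanced_counts_give_zero_lod(self):
        gmap = line_map(1)
        track = lod_scan(PoolCounts([50], [50]), gmap)
        assert np.allclose(track.lod, 0.0)

    def test_hundred_pure_reads(self):
        """100 reads, all 3S: LOD = 100 log10(2) with the MLE at p = 1."""
        gmap = line_map(1)
        track = lod_scan(PoolCounts([0], [100]), gmap)
        assert track.lod.max() == pytest.approx(100 * np.log10(2), rel=1e-9)
        assert track.enriched[np.argmax(track.lod)] == 1

    def test_parent_swap_symmetry(self, gmap, rng):
        cb = rng.poisson(60, gmap.n_snps)
        cs = rng.poisson(90, gmap.n_snps)
        t1 = lod_scan(PoolCounts(cb, cs), gmap)
        t2 = lod_scan(PoolCounts(cs, cb), gmap)
        assert np.allclose(t1.lod, t2.lod)
        assert np.array_equal(t1.enriched, -t2.enriched)

    def test_depth_cap_bounds_lod(self):
        gmap = line_map(1)
        capped = lod_scan(PoolCounts([0], [10000]), gmap, depth_cap=200)
        assert capped.lod.max() == pytest.approx(200 * np.log10(2), rel=1e-9)


def toy_track(lods, signs=None, bin_size=100):
    n = len(lods)
    signs = np.ones(n, dtype=np.int8) if signs is None else np.asarray(signs, dtype=np.int8)
    return LodTrack(
        chrom=np.zeros(n, dtype=int),
        bin_start=np.arange(n) * bin_size,
        lod=np.asarray(lods, dtype=float),
        enriched=signs,
        eff_depth=np.full(n, 200.0),
        bin_size=bin_size,
    )


class TestCallLoci:
    def test_flat_zero_track_yields_nothing(self):
        assert call_loci(toy_track(np.zeros(500))) == []

    def test_run_shorter_than_min_span_discarded(self):
        lods = np.zeros(500)
        lods[100:150] = 10.0  # 5 kb run only
        assert call_loci(toy_track(lods), min_span=20000) == []

    def test_two_lod_drop_interval(self):
        """A 30-kb run peaking at 12 gets an interval delimited by LOD <= 10."""
        lods = np.zeros(600)
        lods[100:400] = 6.0
        lods[180:320] = 11.0
        lods[240:260] = 12.0
        calls = call_loci(toy_track(lods), threshold=5, min_span=20000, drop=2)
        assert len(calls) == 1
        c = calls[0]
        assert c.max_lod == 12.0
        assert c.peak == 240 * 100 + 50  # leftmost argmax bin center
        # nearest bins at LOD <= 10 are 179 and 320
        assert c.start == 179 * 100
        assert c.end == 320 * 100 + 100
        assert c.start <= c.peak < c.end

    def test_enriched_parent_flip_splits_runs(self):
        lods = np.full(600, 8.0)
        signs = np.ones(600, dtype=np.int8)
        signs[300:] = -1
        calls = call_loci(toy_track(lods, signs), threshold=5, min_span=20000, drop=2)
        assert len(calls) == 2
        assert {c.enriched_parent for c in calls} == {"BY", "3S"}

    def test_interval_reaches_chromosome_end_when_lod_stays_high(self):
        lods = np.full(300, 9.0)
        calls = call_loci(toy_track(lods))
        assert calls[0].start == 0
        assert calls[0].end == 300 * 100


class TestPlantedLocusRecovery:
    def test_ns_pool_recovers_fixed_loci(self, gmap, by_design, ruleset, rng):
        """A 100-individual NS pool at 150X calls every class-fixed locus and
        covers the true positions with its support intervals."""
        panel = _class_panel(by_design, ruleset, 100, "NS", rng)
        counts = simulate_pool_counts(panel, 150.0, rng)
        res = BulkSegregantScan(counts, gmap, by_design, n_individuals=100).fit()
        covered = 0
        for name in ("FLO8", "FLO11", "IRA2", "TRR1"):
            snp = by_design.locus_snp[name]
            chrom = gmap.chrom_names[gmap.snp_chrom[snp]]
            pos = int(gmap.snp_pos[snp])
            hits = [c for c in res.loci if c.chromosome == chrom]
            assert hits, f"{name}: no call on {chrom}"
            assert all(c.enriched_parent == "3S" for c in hits)
            covered += any(c.start <= pos < c.end for c in hits)
        # single-replicate smoke check; the >=90% interval-coverage property
        # over 20 replicates lives in the acceptance suite
        assert covered >= 3

    def test_unselected_pools_stay_silent(self):
        clean, n = no_signal_specificity(seed=0, n_replicates=20)
        assert clean / n >= 0.95

    def test_summary_mentions_call_rule(self, gmap, by_design, ruleset, rng):
        panel = _class_panel(by_design, ruleset, 60, "NS", rng)
        counts = simulate_pool_counts(panel, 120.0, rng)
        res = BulkSegregantScan(counts, gmap, by_design, n_individuals=60).fit()
        text = res.summary()
        assert "LOD >= 5.0" in text and "20000" in text
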