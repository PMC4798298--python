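"""Region collapse, pairwise chi-square scan, Storey q-values, partitioning."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from gxemap.genome import GenomeMap
from gxemap.scan import (
    collapse_regions,
    compute_qvalues,
    estimate_pi0,
    exclude_telomeric,
    pairwise_chi2,
    partition_and_call,
    significant_pairs,
    SegregatingRegion,
)


def line_positions(n, spacing=1000):
    chrom = np.zeros(n, dtype=int)
    pos = np.arange(500, 500 + n * spacing, spacing)
    return chrom, pos


def region(chrom, pattern, start=30000, end=31000):
    pattern = np.asarray(pattern, dtype=np.int8)
    return SegregatingRegion(chrom, start, end, np.arange(1), pattern)


class TestCollapseRegions:
    def test_identical_patterns_form_one_region(self):
        m = np.tile([0, 1, 1, 0], (3, 1))
        chrom, pos = line_positions(3)
        regions = collapse_regions(m, chrom, pos)
        assert len(regions) == 1
        assert regions[0].n_snps == 3

    def test_pattern_change_starts_new_region(self):
        m = np.array([[0, 1], [0, 1], [1, 0], [1, 0]], dtype=np.int8)
        chrom, pos = line_positions(4)
        regions = collapse_regions(m, chrom, pos)
        assert [r.n_snps for r in regions] == [2, 2]

    def test_recombinant_individual_breaks_at_switch(self):
        """Toy 5-SNP, 4-individual matrix: one individual recombines after
        SNP 2, producing exactly two regions split at that point."""
        m = np.array(
            [
                [0, 1, 0, 1],
                [0, 1, 0, 1],
                [0, 1, 0, 0],  # individual 3 switched 1 -> 0
                [0, 1, 0, 0],
                [0, 1, 0, 0],
            ],
            dtype=np.int8,
        )
        chrom, pos = line_positions(5)
        regions = collapse_regions(m, chrom, pos)
        assert [list(r.snp_indices) for r in regions] == [[0, 1], [2, 3, 4]]

    def test_chromosome_boundary_always_splits(self):
        m = np.zeros((4, 3), dtype=np.int8)
        chrom = np.array([0, 0, 1, 1])
        pos = np.array([500, 1500, 500, 1500])
        regions = collapse_regions(m, chrom, pos)
        assert [r.chromosome for r in regions] == [0, 1]

    def test_missing_matches_anything_and_consensus_fills(self):
        m = np.array([[0, -1, 1], [0, 1, 1], [-1, 1, 1]], dtype=np.int8)
        chrom, pos = line_positions(3)
        regions = collapse_regions(m, chrom, pos)
        assert len(regions) == 1
        assert list(regions[0].pattern) == [0, 1, 1]

    def test_empty_matrix_raises(self):
        with pytest.raises(ValueError):
            collapse_regions(np.empty((0, 0), dtype=np.int8), [], [])

    @settings(max_examples=50, deadline=None)
    @given(st.integers(0, 2**30))
    def test_collapse_is_lossless_and_bounded(self, seed):
        """Regions reproduce the matrix wherever it was observed, and there
        are never more regions than SNPs."""
        rng = np.random.default_rng(seed)
        n_snps, n_ind = 30, 8
        m = rng.choice([-1, 0, 1], size=(n_snps, n_ind), p=[0.2, 0.4, 0.4]).astype(np.int8)
        chrom, pos = line_positions(n_snps)
        regions = collapse_regions(m, chrom, pos)
        assert len(regions) <= n_snps
        for reg in regions:
            for snp in reg.snp_indices:
                observed = m[snp] != -1
                assert np.array_equal(m[snp][observed], reg.pattern[observed])


class TestTelomereExclusion:
    def make_map(self, length=200000):
        return GenomeMap((("chrI", length),), [0], [length // 2])

    def test_region_at_chromosome_start_dropped(self):
        gmap = self.make_map()
        regions = [region(0, [0, 1], start=100, end=5000)]
        assert exclude_telomeric(regions, gmap, 20000) == []

    def test_mid_chromosome_region_kept(self):
        gmap = self.make_map()
        regions = [region(0, [0, 1], start=90000, end=110000)]
        assert len(exclude_telomeric(regions, gmap, 20000)) == 1

    def test_region_at_chromosome_end_dropped(self):
        gmap = self.make_map()
        regions = [region(0, [0, 1], start=185000, end=199000)]
        assert exclude_telomeric(regions, gmap, 20000) == []

    def test_zero_margin_is_identity(self):
        gmap = self.make_map()
        regions = [region(0, [0, 1], start=0, end=200000)]
        assert exclude_telomeric(regions, gmap, 0) == regions


class TestPairwiseChi2:
    def from_counts(self, a, b, c, d):
        """Two regions on different chromosomes realising the 2x2 table."""
        pat_a = np.array([0] * (a + b) + [1] * (c + d), dtype=np.int8)
        pat_b = np.array([0] * a + [1] * b + [0] * c + [1] * d, dtype=np.int8)
        tests = pairwise_chi2([region(0, pat_a), region(1, pat_b)])
        assert len(tests) == 1
        return tests.iloc[0]

    def test_independent_balanced_table(self):
        row = self.from_counts(25, 25, 25, 25)
        assert row["chi2"] == 0.0
        assert row["p"] == 1.0

    def test_perfect_association_equals_n(self):
        row = self.from_counts(50, 0, 0, 50)
        assert row["chi2"] == pytest.approx(100.0)

    def test_derived_example_equals_twenty(self):
        # 80 * (30*30 - 10*10)^2 / 40^4 = 20
        row = self.from_counts(30, 10, 10, 30)
        assert row["chi2"] == pytest.approx(20.0)

    def test_matches_scipy_contingency(self, rng):
        """Closed form equals scipy's Pearson chi-square without correction."""
        for _ in range(25):
            a, b, c, d = rng.integers(1, 40, size=4)
            row = self.from_counts(int(a), int(b), int(c), int(d))
            expected = stats.chi2_contingency([[a, b], [c, d]], correction=False)
            assert row["chi2"] == pytest.approx(expected.statistic, rel=1e-12)
            assert row["p"] == pytest.approx(expected.pvalue, rel=1e-9)

    def test_zero_margin_pairs_skipped(self):
        pat_a = np.zeros(20, dtype=np.int8)  # constant: zero margin
        pat_b = np.array([0, 1] * 10, dtype=np.int8)
        tests = pairwise_chi2([region(0, pat_a), region(1, pat_b)])
        assert len(tests) == 0

    def test_same_chromosome_pairs_not_tested(self):
        pat = np.array([0, 1] * 10, dtype=np.int8)
        tests = pairwise_chi2([region(0, pat), region(0, 1 - pat)])
        assert len(tests) == 0

    def test_missing_individuals_excluded_pairwise(self):
        pat_a = np.array([0, 0, 1, 1, -1], dtype=np.int8)
        pat_b = np.array([0, 1, 0, 1, 1], dtype=np.int8)
        row = pairwise_chi2([region(0, pat_a), region(1, pat_b)]).iloc[0]
        assert row[["n_bb", "n_bs", "n_sb", "n_ss"]].sum() == 4


def brute_force_qvalues(pvalues, pi0):
    """Literal transcription of the q-value definition, quadratic time."""
    p = list(pvalues)
    m = len(p)
    ranks = {}
    for i, pi in enumerate(p):
        ranks[i] = sum(1 for pj in p if pj <= pi)
    q = []
    for i, pi in enumerate(p):
        candidates = [
            min(1.0, pi0 * m * pj / ranks[j]) for j, pj in enumerate(p) if pj >= pi
        ]
        q.append(min(candidates))
    return np.array(q)


class TestQValues:
    def test_all_ones_stay_one(self):
        assert np.all(compute_qvalues(np.ones(10)) == 1.0)

    def test_monotone_in_p(self, rng):
        for _ in range(10):
            p = rng.uniform(size=50)
            q = compute_qvalues(p)
            order = np.argsort(p)
            assert np.all(np.diff(q[order]) >= -1e-15)

    def test_brute_force_oracle_agreement(self, rng):
        """20 p-values against the literal min-over-tail formula (pi0 = 1
        below the 100-test threshold)."""
        p = np.round(rng.uniform(size=20), 3)
        q = compute_qvalues(p)
        expected = brute_force_qvalues(p, pi0=1.0)
        assert np.allclose(q, expected, atol=1e-12)

    def test_explicit_pi0_scales_uniformly(self, rng):
        p = rng.uniform(size=200)
        q1 = compute_qvalues(p, pi0=1.0)
        qh = compute_qvalues(p, pi0=0.5)
        assert np.allclose(qh, np.minimum(q1 * 0.5, 1.0))

    def test_out_of_range_p_rejected(self):
        with pytest.raises(ValueError):
            compute_qvalues([0.5, 1.5])

    def test_pi0_near_one_for_uniform_nulls(self, rng):
        p = rng.uniform(size=5000)
        assert 0.85 <= estimate_pi0(p) <= 1.0

    def test_pi0_fallback_below_hundred_tests(self, rng):
        assert estimate_pi0(rng.uniform(size=50)) == 1.0


class TestSignificantPairs:
    def test_threshold_zero_selects_nothing(self, rng):
        tests = pd.DataFrame({"chi2": [5.0, 1.0], "p": [0.02, 0.4], "q": [0.3, 0.6]})
        assert len(significant_pairs(tests, 0.0)) == 0

    def test_sorted_by_q_then_chi2(self):
        tests = pd.DataFrame(
            {"chi2": [10.0, 50.0, 30.0], "p": [1e-3, 1e-6, 1e-6], "q": [0.009, 0.001, 0.001]}
        )
        out = significant_pairs(tests, 0.01)
        assert list(out["chi2"]) == [50.0, 30.0, 10.0]

    def test_requires_q_column(self):
        with pytest.raises(ValueError):
            significant_pairs(pd.DataFrame({"p": [0.5]}), 0.01)


class TestPartition:
    def test_fixed_snp_in_subgroup_is_called(self):
        n_ind = 20
        focal_pattern = np.array([0] * 10 + [1] * 10, dtype=np.int8)
        chrom, pos = line_positions(10)
        m = np.zeros((10, n_ind), dtype=np.int8)
        m[:, focal_pattern == 1] = 1  # second group fixed 3S everywhere
        focal = SegregatingRegion(5, 0, 1, np.arange(1), focal_pattern)
        out = partition_and_call(m, chrom, pos, focal, window=3)
        assert (out["3S"]["smoothed"] > 0.9).all()
        assert len(out["3S"]["calls"]) == 1
        assert out["3S"]["calls"].iloc[0]["allele"] == "3S"
        assert len(out["BY"]["calls"]) == 1
        assert out["BY"]["calls"].iloc[0]["allele"] == "BY"

    def test_empty_subgroup_raises_with_allele_name(self):
        focal_pattern = np.ones(6, dtype=np.int8)
        chrom, pos = line_positions(4)
        m = np.zeros((4, 6), dtype=np.int8)
        focal = SegregatingRegion(5, 0, 1, np.arange(1), focal_pattern)
        with pytest.raises(ValueError, match="BY"):
            partition_and_call(m, chrom, pos, focal)

    def test_balanced_snp_not_called(self, rng):
        n_ind = 60
        focal_pattern = np.array([0] * 30 + [1] * 30, dtype=np.int8)
        chrom, pos = line_positions(30)
        m = rng.integers(0, 2, size=(30, n_ind)).astype(np.int8)
        focal = SegregatingRegion(5, 0, 1, np.arange(1), focal_pattern)
        out = partition_and_call(m, chrom, pos, focal, window=25)
        for group in ("BY", "3S"):
            assert len(out[group]["calls"]) == 0


class TestMixtureDissection:
    def test_partition_recovers_minority_genotype_requirements(self, gmap, s3_design, ruleset, rng):
        """In a 70/30 HS mixture of the 3S backcross, the MSS11^3S subgroup
        calls XII^3S, END3^BY, MGA1^BY and SFL1^BY."""
        from gxemap.experiments import _read_space
        from gxemap.scan import HeterogeneityScan
        from gxemap.simulate import simulate_class_mixture

        panel = simulate_class_mixture(
            s3_design, ruleset, 90, "HS", "MSS11", {"BY": 0.7, "3S": 0.3}, rng
        )
        seg_idx = np.flatnonzero(s3_design.read_segregating)
        matrix = _read_space(panel.genomes[:, seg_idx].T)
        res = HeterogeneityScan(matrix, gmap, seg_idx).fit()
        focal = res.region_containing(s3_design.locus_snp["MSS11"])
        part = res.partition(focal)
        called = {}
        for grp in ("BY", "3S"):
            for _, row in part[grp]["calls"].iterrows():
                called.setdefault(grp, []).append((int(row["chromosome"]), row["allele"], row["start"], row["end"]))
        expectations = {"XII": "3S", "END3": "BY", "MGA1": "BY", "SFL1": "BY"}
        for name, allele in expectations.items():
            snp = s3_design.locus_snp[name]
            ci, pos = int(gmap.snp_chrom[snp]), int(gmap.snp_pos[snp])
            assert any(
                c == ci and a == allele and s <= pos < e for c, a, s, e in called["3S"]
            ), f"{name}^{allele} not called in the MSS11^3S subgroup"
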