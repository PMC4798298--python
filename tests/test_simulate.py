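"""Meiosis, screens, scores and sequencing simulators."""

import numpy as np
import pytest

from gxemap.genome import (
    BY,
    MUT,
    S3,
    CrossDesign,
    GenomeMap,
    default_cross_design,
    haldane,
)
from gxemap.rules import RuleSet
from gxemap.simulate import (
    simulate_class_mixture,
    simulate_gamete,
    simulate_gametes,
    simulate_individual_reads,
    simulate_panel,
    simulate_phenotype_scores,
    simulate_pool_counts,
)


def two_snp_design(d_bp, backcross_to="BY"):
    gmap = GenomeMap((("chrI", d_bp + 1000),), [0, 0], [100, 100 + d_bp])
    return CrossDesign(gmap, np.array([S3, S3], dtype=np.int8), backcross_to)


class TestHaldane:
    def test_zero_distance(self):
        assert haldane(0.0) == 0.0

    def test_limit_is_half(self):
        assert haldane(1e9) == pytest.approx(0.5)

    def test_one_centimorgan(self):
        # direct evaluation: (1 - exp(-0.02)) / 2
        assert haldane(3300 / 3300) == pytest.approx(0.009900663, abs=1e-9)

    def test_monotone(self):
        d = np.linspace(0, 500, 100)
        assert np.all(np.diff(haldane(d)) > 0)


class TestMeiosis:
    def test_adjacent_recombinant_fraction_matches_haldane(self, rng):
        d_bp = 33000  # 10 cM
        design = two_snp_design(d_bp)
        g = simulate_gametes(design, 10000, rng)
        obs = (g[:, 0] != g[:, 1]).mean()
        r = haldane(d_bp / 3300)
        se = np.sqrt(r * (1 - r) / 10000)
        assert abs(obs - r) <= 3 * se

    def test_fixed_regions_identical_across_offspring(self, by_design, rng):
        g = simulate_gametes(by_design, 50, rng)
        fixed = ~by_design.segregating
        assert np.all(g[:, fixed] == by_design.focal_parent[fixed])

    def test_first_snp_origin_is_fair(self, rng):
        design = two_snp_design(33000)
        g = simulate_gametes(design, 10000, rng)
        f = (g[:, 0] == S3).mean()
        assert abs(f - 0.5) <= 3 * np.sqrt(0.25 / 10000)

    def test_single_gamete_wrapper(self, by_design, rng):
        g = simulate_gamete(by_design, rng)
        assert g.alleles.shape == (by_design.genome_map.n_snps,)
        assert set(np.unique(g.alleles)) <= {BY, S3, MUT}

    def test_mut_allele_only_at_ira2(self, by_design, rng):
        g = simulate_gametes(by_design, 200, rng)
        mut_cols = np.unique(np.nonzero(g == MUT)[1])
        assert set(mut_cols) <= {by_design.locus_snp["IRA2"]}


class TestPanelScreen:
    def test_unsatisfiable_design_raises(self, gmap, ruleset, rng):
        focal = dict(END3="BY", FLO8="3S", FLO11="3S", IRA2="BY", MGA1="BY",
                     MSS11="BY", SFL1="BY", TRR1="3S", XII="BY")
        design = default_cross_design(gmap, "BY", focal_genotype=focal)
        with pytest.raises(ValueError, match="21"):
            simulate_panel(design, ruleset, 10, 21, rng)

    def test_screen_at_37_collects_only_ns(self, by_design, ruleset, rng):
        panel = simulate_panel(by_design, ruleset, 30, 37, rng)
        assert set(panel.classes) == {"NS"}

    def test_unlinked_snp_frequency_is_half(self, by_design, ruleset, rng):
        """A segregating SNP unlinked to any causal locus stays at 0.5 under screening."""
        gmap = by_design.genome_map
        ci = gmap.chrom_names.index("chrI")  # no causal locus on chrI
        sl = gmap.chrom_slice(ci)
        snp = next(i for i in range(sl.start, sl.stop) if by_design.segregating[i])
        panel = simulate_panel(by_design, ruleset, 200, 21, rng)
        f = (panel.genomes[:, snp] == S3).mean()
        assert abs(f - 0.5) <= 3 * np.sqrt(0.25 / 200)

    def test_class_composition_matches_mendelian_ratios(self, s3_design, ruleset, rng):
        """MS split: the six-allele genotype occurs at 1/4 of the MS class in the
        3S backcross (MS-a-only 3/32 vs MS-b 1/32, derived from the rule table)."""
        panel = simulate_panel(s3_design, ruleset, 600, 21, rng)
        ms = [g for g, c in zip(panel.genotypes, panel.classes) if c == "MS"]
        n = len(ms)
        ms_b = sum(ruleset["MS-b"].satisfied_by(g) for g in ms)
        p = 0.25
        assert abs(ms_b / n - p) <= 3 * np.sqrt(p * (1 - p) / n)

    def test_truth_record_is_json_ready(self, by_design, ruleset, rng):
        import json

        panel = simulate_panel(by_design, ruleset, 5, 21, rng)
        rec = panel.truth_record(seed=1)
        text = json.dumps(rec)
        assert "causal_loci" in json.loads(text)

    def test_mixture_override_hits_requested_proportions(self, s3_design, ruleset, rng):
        panel = simulate_class_mixture(
            s3_design, ruleset, 60, "HS", "MSS11", {"BY": 0.7, "3S": 0.3}, rng
        )
        alleles = [g["MSS11"] for g in panel.genotypes]
        assert alleles.count("BY") == 42
        assert alleles.count("3S") == 18
        assert set(panel.classes) == {"HS"}


class TestPhenotypeScores:
    def test_ns_noise_free_is_rough_everywhere(self, rng):
        s = simulate_phenotype_scores("NS", rng)
        for t in (21, 30, 37):
            assert np.median(s[t]) >= 4

    def test_hs_noise_free_is_rough_only_at_21(self, rng):
        s = simulate_phenotype_scores("HS", rng)
        assert np.median(s[21]) >= 4
        assert np.median(s[30]) <= 1
        assert np.median(s[37]) <= 1

    def test_full_noise_blurs_scores(self, rng):
        draws = [simulate_phenotype_scores("NS", rng, noise=1.0)[37] for _ in range(300)]
        flat = np.concatenate(draws)
        # uniform on {0..5}: all six scores appear, mean near 2.5
        assert set(np.unique(flat)) == {0, 1, 2, 3, 4, 5}
        assert abs(flat.mean() - 2.5) < 0.2

    def test_replicate_count_validated(self, rng):
        with pytest.raises(ValueError):
            simulate_phenotype_scores("NS", rng, replicates=0)


class TestPoolCounts:
    def test_fixed_3s_snp_without_error_has_no_by_reads(self, rng):
        genomes = np.full((20, 50), S3, dtype=np.int8)
        counts = simulate_pool_counts(genomes, 100.0, rng, error_rate=0.0)
        assert np.all(counts.count_by == 0)

    def test_expected_frequency_matches_panel(self, rng):
        n_sites = 10000
        genomes = (np.arange(40)[:, None] % 4 == 0).astype(np.int8) * np.ones((40, n_sites), dtype=np.int8)
        f_true = 0.25
        counts = simulate_pool_counts(genomes, 50.0, rng, error_rate=0.0)
        depth = counts.depth.sum()
        obs = counts.count_3s.sum() / depth
        se = np.sqrt(f_true * (1 - f_true) / depth)
        assert abs(obs - f_true) <= 3 * se

    def test_half_error_rate_erases_signal(self, rng):
        genomes = np.full((20, 5000), S3, dtype=np.int8)
        counts = simulate_pool_counts(genomes, 50.0, rng, error_rate=0.5)
        obs = counts.count_3s.sum() / counts.depth.sum()
        assert abs(obs - 0.5) <= 3 * np.sqrt(0.25 / counts.depth.sum())

    def test_mut_reads_as_3s(self, rng):
        genomes = np.full((10, 100), MUT, dtype=np.int8)
        counts = simulate_pool_counts(genomes, 50.0, rng, error_rate=0.0)
        assert np.all(counts.count_by == 0)


class TestIndividualReads:
    def test_zero_coverage_is_empty(self, by_design, rng):
        g = simulate_gametes(by_design, 1, rng)[0]
        obs = simulate_individual_reads(g, 0.0, rng)
        assert obs.snp_index.size == 0
        assert obs.mean_coverage == 0.0

    def test_realized_coverage_near_target(self, by_design, rng):
        g = simulate_gametes(by_design, 1, rng)[0]
        obs = simulate_individual_reads(g, 1.0, rng)
        n = g.size
        se = np.sqrt(1.0 / n)  # Poisson: var of the mean = lambda / n
        assert abs(obs.mean_coverage - 1.0) <= 3 * se

    def test_error_free_deep_reads_match_truth(self, by_design, rng):
        g = simulate_gametes(by_design, 1, rng)[0]
        obs = simulate_individual_reads(g, 30.0, rng, error_rate=0.0)
        truth_3s = g[obs.snp_index] != BY
        majority_3s = obs.count_3s > obs.count_by
        assert np.array_equal(majority_3s, truth_3s)
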