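"""Replicated simulation experiments used for validation.

These are the study-condition experiments behind the package's headline
checks: null calibration of the pairwise scan, power of the scan on a planted
two-genotype mixture, and locus recovery of the bulk-segregant mapping.  Each
function runs the relevant slice of the pipeline from scratch on freshly
simulated data and returns plain numbers, so the same code backs both the
test suite and ``scripts/acceptance.py``.
"""

from __future__ import annotations

import numpy as np

from .bsa import BulkSegregantScan
from .genome import build_default_map, default_cross_design
from .rules import RuleSet
from .scan import HeterogeneityScan
from .simulate import simulate_class_mixture, simulate_gametes, simulate_panel, simulate_pool_counts


def null_pair_scan(
    seed: int,
    n_panels: int = 50,
    n_individuals: int = 100,
    backcross_to: str = "3S",
    q_threshold: float = 0.01,
    telomere_margin: int = 20000,
):
    """Pairwise chi-square scan on unselected (null) backcross panels.

    Simulates ``n_panels`` independent panels of random segregants with no
    phenotypic screening, runs the full region-collapse / chi-square /
    q-value chain on the true genotypes of each, and pools the counts.

    Returns ``(n_significant, n_tests)`` pooled over all panels; the pooled
    proportion is the realised point-wise false discovery burden and should
    not exceed the q-value threshold.
    """
    rng = np.random.default_rng(seed)
    gmap = build_default_map()
    design = default_cross_design(gmap, backcross_to)
    seg_idx = np.flatnonzero(design.read_segregating)
    n_sig = n_tests = 0
    for _ in range(n_panels):
        genomes = simulate_gametes(design, n_individuals, rng)
        matrix = _read_space(genomes[:, seg_idx].T)
        res = HeterogeneityScan(matrix, gmap, seg_idx).fit(telomere_margin, q_threshold)
        n_sig += len(res.significant)
        n_tests += res.n_tests
    return n_sig, n_tests


def mixture_power_scan(
    seed: int,
    n_replicates: int = 20,
    n_individuals: int = 90,
    minority_fraction: float = 0.30,
    backcross_to: str = "3S",
    focal_locus: str = "MSS11",
    q_threshold: float = 0.01,
):
    """Scan power on a planted two-genotype HS mixture.

    Each replicate simulates ``n_individuals`` HS-class segregants of the 3S
    backcross with the MSS11^BY : MSS11^3S group mixture overridden to
    (1 - minority_fraction) : minority_fraction, then runs the heterogeneity
    scan on the true genotypes.  A replicate counts as a recovery when at
    least one significant pair links the region containing the focal locus
    (MSS11) to a region containing another causal locus — the event the
    partition step of the analysis is anchored on.

    Returns ``(n_recovered, n_replicates)``.
    """
    rng = np.random.default_rng(seed)
    gmap = build_default_map()
    design = default_cross_design(gmap, backcross_to)
    ruleset = RuleSet.default()
    seg_idx = np.flatnonzero(design.read_segregating)
    proportions = {"BY": 1.0 - minority_fraction, "3S": minority_fraction}
    recovered = 0
    for _ in range(n_replicates):
        panel = simulate_class_mixture(
            design, ruleset, n_individuals, "HS", focal_locus, proportions, rng
        )
        matrix = _read_space(panel.genomes[:, seg_idx].T)
        res = HeterogeneityScan(matrix, gmap, seg_idx).fit()
        if _focal_pair_found(res, design, focal_locus):
            recovered += 1
    return recovered, n_replicates


def _focal_pair_found(res, design, focal_locus: str) -> bool:
    region_of = {name: res.region_containing(snp) for name, snp in design.locus_snp.items()}
    focal_region = region_of.get(focal_locus)
    if focal_region is None:
        return False
    other_regions = {r for name, r in region_of.items() if name != focal_locus and r is not None}
    for _, row in res.significant.iterrows():
        pair = {int(row["region_a"]), int(row["region_b"])}
        if focal_region in pair and pair & other_regions:
            return True
    return False


def bsa_recovery(
    seed: int,
    n_replicates: int = 20,
    n_pooled: int = 100,
    mean_depth: float = 150.0,
    backcross_to: str = "BY",
    class_label: str = "NS",
):
    """Locus recovery of bulk mapping on phenotype-selected pools.

    Each replicate screens a fresh panel of ``n_pooled`` individuals of the
    requested class, sequences the pool, and scans it.  A causal locus counts
    as *planted* when its required allele is fixed in the class under the
    backcross design (read space); recovery asks that each planted locus'
    chromosome carries a call and that the support interval covers the true
    position.

    Returns a dict with per-replicate tallies:
    ``n_planted`` loci per replicate, ``called`` (loci with a call on their
    chromosome, summed), ``covered`` (support interval contains the truth,
    summed), plus the totals.
    """
    rng = np.random.default_rng(seed)
    gmap = build_default_map()
    design = default_cross_design(gmap, backcross_to)
    ruleset = RuleSet.default()
    planted = _fixed_in_class(design, ruleset, class_label)
    called = covered = 0
    for _ in range(n_replicates):
        panel = _class_panel(design, ruleset, n_pooled, class_label, rng)
        counts = simulate_pool_counts(panel, mean_depth, rng)
        res = BulkSegregantScan(counts, gmap, design, n_individuals=n_pooled).fit()
        for name in planted:
            snp = design.locus_snp[name]
            chrom = gmap.chrom_names[gmap.snp_chrom[snp]]
            pos0 = int(gmap.snp_pos[snp])
            on_chrom = [c for c in res.loci if c.chromosome == chrom]
            if on_chrom:
                called += 1
                if any(c.start <= pos0 < c.end for c in on_chrom):
                    covered += 1
    n_total = len(planted) * n_replicates
    return {
        "planted_loci": sorted(planted),
        "n_total": n_total,
        "called": called,
        "covered": covered,
    }


def six_pool_union(seed: int, n_pooled: int = 100, mean_depth: float = 150.0):
    """Distinct causal loci detected across the six class/backcross pools.

    Simulates the HS, MS and NS pools of both backcrosses once each and
    counts the causal loci whose true position is covered by any call's
    support interval.  Mirrors the real study's tally of eight distinct loci
    across its six pools.
    """
    rng = np.random.default_rng(seed)
    gmap = build_default_map()
    ruleset = RuleSet.default()
    union = set()
    for bc in ("BY", "3S"):
        design = default_cross_design(gmap, bc)
        for cls in ("HS", "MS", "NS"):
            panel = _class_panel(design, ruleset, n_pooled, cls, rng)
            counts = simulate_pool_counts(panel, mean_depth, rng)
            res = BulkSegregantScan(counts, gmap, design, n_individuals=n_pooled).fit()
            for name, snp in design.locus_snp.items():
                chrom = gmap.chrom_names[gmap.snp_chrom[snp]]
                pos0 = int(gmap.snp_pos[snp])
                if any(c.chromosome == chrom and c.start <= pos0 < c.end for c in res.loci):
                    union.add(name)
    return sorted(union)


def no_signal_specificity(
    seed: int,
    n_replicates: int = 20,
    n_pooled: int = 100,
    mean_depth: float = 150.0,
    backcross_to: str = "BY",
):
    """Fraction of unselected pools yielding zero locus calls."""
    rng = np.random.default_rng(seed)
    gmap = build_default_map()
    design = default_cross_design(gmap, backcross_to)
    clean = 0
    for _ in range(n_replicates):
        genomes = simulate_gametes(design, n_pooled, rng)
        counts = simulate_pool_counts(genomes, mean_depth, rng)
        res = BulkSegregantScan(counts, gmap, design, n_individuals=n_pooled).fit()
        if len(res.loci) == 0:
            clean += 1
    return clean, n_replicates


# ---------------------------------------------------------------------------


def _read_space(matrix: np.ndarray) -> np.ndarray:
    """Collapse MUT (code 2) onto 3S (code 1) for read-level analyses."""
    out = matrix.astype(np.int8).copy()
    out[out == 2] = 1
    return out


def _class_panel(design, ruleset, n, class_label, rng, batch=2048, max_examined=5_000_000):
    """Genomes of ``n`` segregants of exactly the requested class."""
    from .rules import classify

    rows = []
    examined = 0
    while len(rows) < n:
        if examined >= max_examined:
            raise RuntimeError(f"could not collect {n} {class_label} individuals")
        g = simulate_gametes(design, batch, rng)
        examined += batch
        for row in g:
            if classify(design.genotype_of(row), ruleset) == class_label:
                rows.append(row)
                if len(rows) == n:
                    break
    return np.array(rows, dtype=np.int8)


def _fixed_in_class(design, ruleset, class_label) -> list:
    """Causal loci whose read-space allele is constant within a class.

    Brute-force over the 2^k genotype table of the design's segregating loci:
    a locus is 'planted' for a class when every genotype of that class
    carries the same read-space allele there and that allele differs from
    0.5-frequency expectation (i.e. the locus segregates in the design).
    """
    from .genome import READ_CODE, ALLELE_CODES
    from .rules import classify, enumerate_genotypes

    locus_design = design.to_locus_design()
    seen = {}
    for g in enumerate_genotypes(locus_design):
        if classify(g, ruleset) != class_label:
            continue
        for name, allele in g.items():
            seen.setdefault(name, set()).add(READ_CODE[ALLELE_CODES[allele]])
    if not seen:
        raise ValueError(f"class {class_label} is unreachable under this design")
    planted = []
    for name, alleles in seen.items():
        kind, _ = locus_design.statuses[name]
        if kind == "segregating" and len(alleles) == 1 and design.read_segregating[design.locus_snp[name]]:
            planted.append(name)
    return planted
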