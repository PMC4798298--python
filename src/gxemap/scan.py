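"""Pairwise scan for genotypic heterogeneity within a phenotype class.

When two different multi-locus genotypes produce the same phenotype, the
alleles specific to each genotype become correlated across individuals of the
class.  The scan works on a genotype matrix of class-pure segregants:

1. linked SNPs with the same inheritance pattern collapse into segregating
   regions (one statistical unit each, cutting the number of tests);
2. regions within 20 kb of chromosome ends are excluded;
3. every *inter*-chromosomal region pair is tested for association with a
   Pearson chi-square on the 2x2 table of joint allele states (df = 1, no
   continuity correction) — intra-chromosomal correlation is linkage, not
   epistasis;
4. p-values convert to Storey q-values and pairs at q <= 0.01 are declared
   significant;
5. detected pairs are dissected by partitioning the panel on its genotype at
   a focal region and calling loci where a subgroup's smoothed allele
   frequency leaves the [10%, 90%] band.

:class:`HeterogeneityScan` wraps steps 1-4 as a model object whose ``fit()``
returns :class:`HeterogeneityScanResults`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import UnivariateSpline

from .genome import GenomeMap
from .hmm import MISSING


@dataclass(frozen=True)
class SegregatingRegion:
    """Maximal run of linked SNPs sharing one inheritance pattern.

    ``pattern`` holds one value per individual (BY/3S codes, -1 missing): the
    consensus over member SNPs, with missing entries filled by any member
    that observed them.  Coordinates are 0-based half-open.
    """

    chromosome: int
    start: int
    end: int
    snp_indices: np.ndarray
    pattern: np.ndarray

    @property
    def n_snps(self) -> int:
        return int(self.snp_indices.size)


def collapse_regions(matrix: np.ndarray, chrom: np.ndarray, pos: np.ndarray) -> list:
    """Greedy left-to-right collapse of identically inherited SNPs.

    ``matrix`` is (SNPs x individuals) over segregating SNPs only, with -1
    marking missing calls; ``chrom``/``pos`` give each SNP's chromosome index
    and 0-based position.  A SNP joins the current region iff its pattern
    matches the region's consensus wherever both are non-missing (missing
    matches anything); otherwise a new region starts.
    """
    matrix = np.asarray(matrix, dtype=np.int8)
    if matrix.size == 0 or matrix.shape[1] == 0:
        raise ValueError("empty genotype matrix")
    if matrix.shape[0] != len(chrom) or matrix.shape[0] != len(pos):
        raise ValueError("matrix rows must align with chrom/pos")
    regions = []
    consensus = None
    members = []
    cur_chrom = None

    def _flush():
        if members:
            snps = np.array(members, dtype=np.int64)
            regions.append(
                SegregatingRegion(
                    chromosome=int(cur_chrom),
                    start=int(pos[members[0]]),
                    end=int(pos[members[-1]]) + 1,
                    snp_indices=snps,
                    pattern=consensus.copy(),
                )
            )

    for i in range(matrix.shape[0]):
        row = matrix[i]
        if cur_chrom != chrom[i]:
            _flush()
            cur_chrom, consensus, members = chrom[i], row.copy(), [i]
            continue
        ok = np.all((consensus == row) | (consensus == MISSING) | (row == MISSING))
        if ok:
            members.append(i)
            np.copyto(consensus, row, where=consensus == MISSING)
        else:
            _flush()
            consensus, members = row.copy(), [i]
    _flush()
    return regions


def exclude_telomeric(regions, genome_map: GenomeMap, margin: int = 20000) -> list:
    """Drop regions overlapping the first or last ``margin`` bp of a chromosome."""
    kept = []
    for reg in regions:
        length = genome_map.chrom_length(reg.chromosome)
        if reg.start < margin or reg.end > length - margin:
            continue
        kept.append(reg)
    return kept


def pairwise_chi2(regions) -> pd.DataFrame:
    """Chi-square association tests over all inter-chromosomal region pairs.

    For each pair, individuals non-missing at both regions form a 2x2 table
    of joint allele states; the statistic is the closed-form Pearson
    chi-square ``N (ad - bc)^2 / (r1 r2 c1 c2)`` with df = 1 and no
    continuity correction.  Pairs with a zero margin are skipped (the test is
    undefined there).
    """
    R = len(regions)
    if R < 2:
        return _empty_tests()
    P = np.stack([r.pattern for r in regions]).astype(np.int8)
    chroms = np.array([r.chromosome for r in regions])
    Bm = (P == 0).astype(np.float64)
    Sm = (P == 1).astype(np.float64)
    a = Bm @ Bm.T
    b = Bm @ Sm.T
    c = Sm @ Bm.T
    d = Sm @ Sm.T
    n = a + b + c + d
    r1, r2, c1, c2 = a + b, c + d, a + c, b + d
    iu = np.triu_indices(R, k=1)
    inter = chroms[iu[0]] != chroms[iu[1]]
    margins_ok = (r1 > 0) & (r2 > 0) & (c1 > 0) & (c2 > 0)
    keep = inter & margins_ok[iu]
    ia, ib = iu[0][keep], iu[1][keep]
    num = a[ia, ib] * d[ia, ib] - b[ia, ib] * c[ia, ib]
    denom = r1[ia, ib] * r2[ia, ib] * c1[ia, ib] * c2[ia, ib]
    chi2 = n[ia, ib] * num**2 / denom
    p = stats.chi2.sf(chi2, df=1)
    return pd.DataFrame(
        {
            "region_a": ia,
            "region_b": ib,
            "n_bb": a[ia, ib].astype(int),
            "n_bs": b[ia, ib].astype(int),
            "n_sb": c[ia, ib].astype(int),
            "n_ss": d[ia, ib].astype(int),
            "chi2": chi2,
            "p": p,
        }
    )


def _empty_tests() -> pd.DataFrame:
    return pd.DataFrame(
        {k: pd.Series(dtype=t) for k, t in
         [("region_a", int), ("region_b", int), ("n_bb", int), ("n_bs", int),
          ("n_sb", int), ("n_ss", int), ("chi2", float), ("p", float)]}
    )


def estimate_pi0(pvalues: np.ndarray, lambdas: np.ndarray | None = None) -> float:
    """Storey's null-proportion estimate via the lambda-grid smoother.

    ``pi0(lambda) = #{p > lambda} / (m (1 - lambda))`` over the grid
    lambda = 0.05, 0.10, ..., 0.95, smoothed with a cubic spline and read off
    at the last grid point.  Falls back to 1 (plain Benjamini-Hochberg
    behaviour) for fewer than 100 tests or when the estimate leaves (0, 1].
    """
    p = np.asarray(pvalues, dtype=float)
    m = p.size
    if m < 100:
        return 1.0
    if lambdas is None:
        lambdas = np.arange(0.05, 0.96, 0.05)
    raw = np.array([(p > lam).mean() / (1.0 - lam) for lam in lambdas])
    spline = UnivariateSpline(lambdas, raw, k=3)
    pi0 = float(spline(lambdas[-1]))
    if not np.isfinite(pi0) or pi0 <= 0 or pi0 > 1:
        return 1.0
    return pi0


def compute_qvalues(pvalues, pi0: float | None = None) -> np.ndarray:
    """Storey q-values: ``q_i = min_{p_j >= p_i} pi0 * m * p_j / rank(p_j)``.

    Monotone non-decreasing in p and capped at 1.  ``pi0`` defaults to
    :func:`estimate_pi0`.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if pi0 is None:
        pi0 = estimate_pi0(p)
    m = p.size
    order = np.argsort(p, kind="stable")
    ranks = np.arange(1, m + 1)
    q_sorted = pi0 * m * p[order] / ranks
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def significant_pairs(tests: pd.DataFrame, q_threshold: float = 0.01) -> pd.DataFrame:
    """Pairs at q <= threshold, strongest first (by q, then chi2 descending)."""
    if "q" not in tests.columns:
        raise ValueError("tests must carry a 'q' column (run compute_qvalues first)")
    hits = tests[tests["q"] <= q_threshold]
    return hits.sort_values(["q", "chi2"], ascending=[True, False]).reset_index(drop=True)


def partition_and_call(
    matrix: np.ndarray,
    chrom: np.ndarray,
    pos: np.ndarray,
    focal: SegregatingRegion,
    window: int = 25,
    low: float = 0.10,
    high: float = 0.90,
) -> dict:
    """Split the panel by genotype at a focal region and call skewed loci.

    Individuals missing at the focal region are dropped; each remaining
    subgroup (focal allele BY or 3S) gets a per-SNP 3S-allele frequency
    track, smoothed over ``window``-SNP sliding windows within chromosomes.
    SNPs with smoothed frequency below ``low`` or above ``high`` are called,
    and adjacent called SNPs with the same direction merge into intervals.
    Raises ``ValueError`` naming the allele if a subgroup is empty.
    """
    from .bsa import _smooth_within_groups
    from .genome import ALLELE_NAMES

    matrix = np.asarray(matrix, dtype=np.int8)
    out = {}
    for code in (0, 1):
        members = np.flatnonzero(focal.pattern == code)
        allele = ALLELE_NAMES[code]
        if members.size == 0:
            raise ValueError(f"no individuals carry the {allele} allele at the focal region")
        sub = matrix[:, members]
        counts_3s = (sub == 1).sum(axis=1).astype(float)
        informative = (sub != MISSING).sum(axis=1).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            freq = np.where(informative > 0, counts_3s / informative, np.nan)
        smoothed = _smooth_within_groups(freq, np.asarray(chrom), window)
        called_low = smoothed < low
        called_high = smoothed > high
        calls = _merge_called(called_low, called_high, chrom, pos)
        out[allele] = {
            "n_individuals": int(members.size),
            "frequency": freq,
            "smoothed": smoothed,
            "calls": calls,
        }
    return out


def _merge_called(low_mask, high_mask, chrom, pos) -> pd.DataFrame:
    """Merge runs of adjacent called SNPs (same direction) into intervals."""
    direction = np.zeros(len(chrom), dtype=np.int8)
    direction[low_mask] = -1
    direction[high_mask] = 1
    rows = []
    i = 0
    n = len(chrom)
    while i < n:
        if direction[i] == 0:
            i += 1
            continue
        j = i
        while j + 1 < n and direction[j + 1] == direction[i] and chrom[j + 1] == chrom[i]:
            j += 1
        rows.append(
            {
                "chromosome": int(chrom[i]),
                "start": int(pos[i]),
                "end": int(pos[j]) + 1,
                "allele": "BY" if direction[i] < 0 else "3S",
                "n_snps": j - i + 1,
            }
        )
        i = j + 1
    return pd.DataFrame(rows, columns=["chromosome", "start", "end", "allele", "n_snps"])


class HeterogeneityScan:
    """Pairwise chi-square scan model over a class-pure genotype matrix.

    Parameters
    ----------
    matrix
        (segregating SNPs x individuals) matrix of BY/3S codes, -1 missing.
    genome_map
        Marker map; ``snp_index`` gives the matrix rows' SNP indices.
    snp_index
        Map SNP index of each matrix row.
    """

    def __init__(self, matrix: np.ndarray, genome_map: GenomeMap, snp_index: np.ndarray):
        self.matrix = np.asarray(matrix, dtype=np.int8)
        self.genome_map = genome_map
        self.snp_index = np.asarray(snp_index, dtype=np.int64)
        if self.matrix.shape[0] != self.snp_index.size:
            raise ValueError("matrix rows must align with snp_index")

    def fit(self, telomere_margin: int = 20000, q_threshold: float = 0.01) -> "HeterogeneityScanResults":
        chrom = self.genome_map.snp_chrom[self.snp_index]
        pos = self.genome_map.snp_pos[self.snp_index]
        regions = collapse_regions(self.matrix, chrom, pos)
        regions = exclude_telomeric(regions, self.genome_map, telomere_margin)
        tests = pairwise_chi2(regions)
        if len(tests):
            tests = tests.assign(q=compute_qvalues(tests["p"].to_numpy()))
        else:
            tests = tests.assign(q=pd.Series(dtype=float))
        sig = significant_pairs(tests, q_threshold)
        return HeterogeneityScanResults(self, regions, tests, sig, q_threshold, chrom, pos)


class HeterogeneityScanResults:
    """Regions, pair tests and significant pairs from a heterogeneity scan."""

    def __init__(self, model, regions, tests, significant, q_threshold, chrom, pos):
        self.model = model
        self.regions = regions
        self.tests = tests
        self.significant = significant
        self.q_threshold = q_threshold
        self._chrom = chrom
        self._pos = pos

    @property
    def n_regions(self) -> int:
        return len(self.regions)

    @property
    def n_tests(self) -> int:
        return len(self.tests)

    def region_containing(self, snp_index: int):
        """Index of the region containing a map SNP, or None."""
        row = np.searchsorted(self.model.snp_index, snp_index)
        if row >= self.model.snp_index.size or self.model.snp_index[row] != snp_index:
            return None
        for i, reg in enumerate(self.regions):
            if row in reg.snp_indices:
                return i
        return None

    def partition(self, focal_region: int, window: int = 25, low: float = 0.10, high: float = 0.90) -> dict:
        """Dissect heterogeneity by splitting on the genotype at a region."""
        return partition_and_call(
            self.model.matrix, self._chrom, self._pos, self.regions[focal_region], window, low, high
        )

    def summary(self) -> str:
        gmap = self.model.genome_map
        lines = [
            "Pairwise genotypic-heterogeneity scan",
            "=" * 64,
            f"Individuals:        {self.model.matrix.shape[1]}",
            f"Segregating SNPs:   {self.model.matrix.shape[0]}",
            f"Segregating regions:{self.n_regions:>6}",
            f"Inter-chrom tests:  {self.n_tests}",
            f"Significant pairs (q <= {self.q_threshold}): {len(self.significant)}",
            "-" * 64,
        ]
        if len(self.significant):
            view = self.significant.copy()
            for col in ("region_a", "region_b"):
                view[col + "_chrom"] = [
                    gmap.chrom_names[self.regions[i].chromosome] for i in view[col]
                ]
            lines.append(
                view[["region_a_chrom", "region_b_chrom", "chi2", "p", "q"]].to_string(index=False)
            )
        else:
            lines.append("(no significant pairs)")
        return "\n".join(lines)
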