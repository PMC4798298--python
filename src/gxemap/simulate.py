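"""Synthetic backcross panels, phenotype screens, and sequencing read counts.

Meiosis is a Markov walk along each chromosome: a gamete inherits each SNP
from the focal or the recurrent parental haplotype, switching between the two
with the Haldane recombination fraction of the inter-SNP distance (at the
map's bp-per-centimorgan scale).  Screens, pooled sequencing of
phenotype-selected pools, and ~1X whole-genome sequencing of single segregants
are layered on top with Poisson depth and a symmetric per-read error rate.

Every simulation takes an explicit ``numpy.random.Generator``; nothing here
owns global random state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genome import BY, MUT, S3, ALLELE_NAMES, CrossDesign, GenomeMap, haldane
from .rules import RuleSet, classify, expected_frequency


@dataclass(frozen=True)
class SegregantGenome:
    """Per-SNP allele vector (BY/3S/MUT codes) of one backcross offspring."""

    alleles: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "alleles", np.asarray(self.alleles, dtype=np.int8))


@dataclass(frozen=True)
class PoolCounts:
    """Pooled-sequencing read counts per SNP, in read space (BY vs 3S).

    ``snp_index`` maps rows to SNP indices of the genome map; ``None`` means
    all SNPs in map order.
    """

    count_by: np.ndarray
    count_3s: np.ndarray
    snp_index: np.ndarray | None = None

    def __post_init__(self):
        object.__setattr__(self, "count_by", np.asarray(self.count_by, dtype=np.int64))
        object.__setattr__(self, "count_3s", np.asarray(self.count_3s, dtype=np.int64))
        if self.snp_index is not None:
            object.__setattr__(self, "snp_index", np.asarray(self.snp_index, dtype=np.int64))
        if self.count_by.shape != self.count_3s.shape:
            raise ValueError("count arrays must have equal length")
        if np.any(self.count_by < 0) or np.any(self.count_3s < 0):
            raise ValueError("read counts must be non-negative")

    @property
    def n_sites(self) -> int:
        return int(self.count_by.size)

    @property
    def depth(self) -> np.ndarray:
        return self.count_by + self.count_3s

    def indices(self) -> np.ndarray:
        if self.snp_index is not None:
            return self.snp_index
        return np.arange(self.n_sites, dtype=np.int64)


@dataclass(frozen=True)
class SiteObservations:
    """Sparse per-individual read counts: (SNP index, count_BY, count_3S)."""

    snp_index: np.ndarray
    count_by: np.ndarray
    count_3s: np.ndarray
    n_snps: int

    def __post_init__(self):
        object.__setattr__(self, "snp_index", np.asarray(self.snp_index, dtype=np.int64))
        object.__setattr__(self, "count_by", np.asarray(self.count_by, dtype=np.int64))
        object.__setattr__(self, "count_3s", np.asarray(self.count_3s, dtype=np.int64))
        if np.any(self.count_by < 0) or np.any(self.count_3s < 0):
            raise ValueError("read counts must be non-negative")

    @property
    def mean_coverage(self) -> float:
        """Total reads divided by the number of map SNPs."""
        if self.n_snps == 0:
            return 0.0
        return float((self.count_by.sum() + self.count_3s.sum()) / self.n_snps)


@dataclass
class Panel:
    """A collection of screened segregants with their true labels.

    ``genomes`` is an ``(n, n_snps)`` int8 allele matrix; ``classes`` the true
    sensitivity class of each individual; ``genotypes`` their multi-locus
    genotype vectors at the named causal loci; ``n_examined`` how many random
    segregants were inspected to collect the panel.
    """

    design: CrossDesign
    genomes: np.ndarray
    classes: list
    genotypes: list
    n_examined: int = 0
    ids: list = field(default_factory=list)

    def __post_init__(self):
        if not self.ids:
            self.ids = [f"seg{i:04d}" for i in range(len(self.classes))]

    @property
    def n(self) -> int:
        return self.genomes.shape[0]

    def allele_frequency_3s(self) -> np.ndarray:
        """Read-space 3S allele frequency per SNP across the panel."""
        return (self.genomes != BY).mean(axis=0)

    def truth_record(self, seed=None) -> dict:
        """Machine-readable ground truth consumed by evaluation code."""
        gmap = self.design.genome_map
        loci = []
        for name, snp in sorted(self.design.locus_snp.items()):
            ci = int(gmap.snp_chrom[snp])
            loci.append(
                {
                    "name": name,
                    "chromosome": gmap.chrom_names[ci],
                    "position": int(gmap.snp_pos[snp]) + 1,  # 1-based on disk
                    "snp_index": int(snp),
                    "focal_allele": ALLELE_NAMES[int(self.design.focal_parent[snp])],
                }
            )
        individuals = [
            {"id": self.ids[i], "class": self.classes[i], "genotype": self.genotypes[i]}
            for i in range(self.n)
        ]
        rec = {
            "backcross_to": self.design.backcross_to,
            "n_examined": int(self.n_examined),
            "causal_loci": loci,
            "individuals": individuals,
        }
        if seed is not None:
            rec["seed"] = int(seed)
        return rec


# ---------------------------------------------------------------------------
# Meiosis


def simulate_gametes(design: CrossDesign, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw ``n`` backcross offspring genomes as an ``(n, n_snps)`` int8 array.

    Within each chromosome the parental origin of the first SNP is
    Bernoulli(1/2) and switches between adjacent SNPs with probability
    r(d) = (1 - exp(-2 d_cM/100))/2 (Haldane), d_cM = d_bp / map_scale.
    Fixed regions (focal allele equal to the recurrent parent's) come out
    identical in every offspring by construction.
    """
    gmap = design.genome_map
    if gmap.n_snps == 0:
        raise ValueError("empty genome map")
    out = np.empty((n, gmap.n_snps), dtype=np.int8)
    recurrent = design.recurrent_code
    for ci in range(gmap.n_chromosomes):
        sl = gmap.chrom_slice(ci)
        m = sl.stop - sl.start
        if m == 0:
            continue
        r = gmap.recomb_fractions(ci)
        first = rng.integers(0, 2, size=(n, 1), dtype=np.int8)
        if m > 1:
            switches = (rng.random((n, m - 1)) < r).astype(np.int8)
            origin = np.concatenate([first, switches], axis=1)
            origin = np.cumsum(origin, axis=1, dtype=np.int64) % 2
        else:
            origin = first.astype(np.int64)
        focal = design.focal_parent[sl]
        out[:, sl] = np.where(origin == 0, focal[np.newaxis, :], np.int8(recurrent))
    return out


def simulate_gamete(design: CrossDesign, rng: np.random.Generator) -> SegregantGenome:
    """Single-offspring convenience wrapper around :func:`simulate_gametes`."""
    return SegregantGenome(simulate_gametes(design, 1, rng)[0])


# ---------------------------------------------------------------------------
# Screens


def _screen_frequency(design: CrossDesign, ruleset: RuleSet, temperature: int) -> float:
    """Upper bound on the fraction of random offspring rough at ``temperature``."""
    locus_design = design.to_locus_design()
    return sum(
        expected_frequency(rule, locus_design)
        for rule in ruleset
        if temperature in rule.temperatures
    )


def simulate_panel(
    design: CrossDesign,
    ruleset: RuleSet,
    n: int,
    screen_temperature: int,
    rng: np.random.Generator,
    batch: int = 512,
    max_examined: int = 2_000_000,
) -> Panel:
    """Collect ``n`` segregants expressing the trait at ``screen_temperature``.

    Random offspring are drawn and kept when their multi-locus genotype
    expresses the rough phenotype at the screening temperature (per the rule
    set); each kept individual is labelled with its true sensitivity class.
    Raises ``ValueError`` if no rule active at that temperature has positive
    Mendelian frequency under the design.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if _screen_frequency(design, ruleset, screen_temperature) == 0.0:
        raise ValueError(
            f"no genotype satisfiable under this design expresses the trait at {screen_temperature} C"
        )
    kept, classes, genotypes = [], [], []
    examined = 0
    from .rules import expressed_temperatures

    while len(classes) < n:
        if examined >= max_examined:
            raise RuntimeError("screen exceeded max_examined without filling the panel")
        g = simulate_gametes(design, batch, rng)
        examined += batch
        for row in g:
            geno = design.genotype_of(row)
            temps = expressed_temperatures(geno, ruleset)
            if screen_temperature in temps:
                kept.append(row)
                classes.append(classify(geno, ruleset))
                genotypes.append(geno)
                if len(classes) == n:
                    break
    return Panel(design, np.array(kept, dtype=np.int8), classes, genotypes, n_examined=examined)


def simulate_class_mixture(
    design: CrossDesign,
    ruleset: RuleSet,
    n: int,
    class_label: str,
    focal_locus: str,
    proportions: dict,
    rng: np.random.Generator,
    batch: int = 2048,
    max_examined: int = 5_000_000,
) -> Panel:
    """Class-pure panel with overridden genotype-group mixture proportions.

    Individuals of ``class_label`` are split by their allele at
    ``focal_locus`` and collected into quotas ``round(n * proportions[allele])``.
    This overrides the Mendelian group ratio — real screens showed mixture
    proportions that deviate from expectation — so scan power can be studied
    at a chosen minority fraction (e.g. 70/30 MSS11^BY vs MSS11^3S in the HS
    class of the 3S backcross).
    """
    quotas = {a: int(round(n * p)) for a, p in proportions.items()}
    if sum(quotas.values()) != n:
        a0 = max(quotas, key=lambda a: proportions[a])
        quotas[a0] += n - sum(quotas.values())
    got = {a: [] for a in quotas}
    classes_all, genotypes_all, rows_all = [], [], []
    examined = 0
    from .rules import expressed_temperatures  # noqa: F401  (kept symmetric with simulate_panel)

    while any(len(got[a]) < quotas[a] for a in quotas):
        if examined >= max_examined:
            raise RuntimeError("mixture screen exceeded max_examined")
        g = simulate_gametes(design, batch, rng)
        examined += batch
        for row in g:
            geno = design.genotype_of(row)
            if classify(geno, ruleset) != class_label:
                continue
            allele = geno.get(focal_locus)
            if allele in quotas and len(got[allele]) < quotas[allele]:
                got[allele].append((row, geno))
    for allele in sorted(quotas):
        for row, geno in got[allele]:
            rows_all.append(row)
            genotypes_all.append(geno)
            classes_all.append(class_label)
    return Panel(design, np.array(rows_all, dtype=np.int8), classes_all, genotypes_all, n_examined=examined)


# ---------------------------------------------------------------------------
# Phenotype scores


def simulate_phenotype_scores(
    class_label: str,
    rng: np.random.Generator,
    replicates: int = 3,
    noise: float = 0.0,
    temperatures=(21, 30, 37),
) -> dict:
    """Replicate 0-5 colony scores per temperature for one individual.

    Temperatures in the class's permissive set draw from the rough score
    distribution (uniform on {4, 5}); the rest draw from the smooth one
    (uniform on {0, 1}).  With probability ``noise`` a replicate is replaced
    by a uniform draw on {0..5}, blurring the classes.
    """
    from .rules import TEMPS_BY_CLASS

    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    if class_label not in TEMPS_BY_CLASS:
        raise ValueError(f"unknown class label {class_label!r}")
    expressed = TEMPS_BY_CLASS[class_label]
    scores = {}
    for t in temperatures:
        lo = 4 if t in expressed else 0
        s = rng.integers(lo, lo + 2, size=replicates)
        if noise > 0:
            blur = rng.random(replicates) < noise
            s = np.where(blur, rng.integers(0, 6, size=replicates), s)
        scores[t] = [int(x) for x in s]
    return scores


# ---------------------------------------------------------------------------
# Sequencing


def simulate_pool_counts(
    genomes: np.ndarray,
    mean_depth: float,
    rng: np.random.Generator,
    error_rate: float = 0.005,
) -> PoolCounts:
    """Pooled sequencing of equal-representation panel members.

    Per SNP, depth ~ Poisson(mean_depth) and each read comes from a uniformly
    random panel member, reporting that member's read-space allele (MUT
    collapses to 3S) flipped with probability ``error_rate``.  Uniform member
    assignment makes the 3S read count exactly Binomial(depth, f(1-e)+(1-f)e)
    where f is the panel 3S frequency, which is how it is drawn.
    """
    genomes = np.asarray(genomes)
    if genomes.ndim != 2 or genomes.shape[0] == 0:
        raise ValueError("panel must be a non-empty (n, n_snps) matrix")
    if mean_depth <= 0:
        raise ValueError("mean_depth must be positive")
    f = (genomes != BY).mean(axis=0)  # read-space 3S frequency
    p = f * (1.0 - error_rate) + (1.0 - f) * error_rate
    depth = rng.poisson(mean_depth, size=genomes.shape[1])
    c3s = rng.binomial(depth, p)
    return PoolCounts(depth - c3s, c3s)


def simulate_individual_reads(
    alleles: np.ndarray,
    mean_coverage: float,
    rng: np.random.Generator,
    error_rate: float = 0.005,
) -> SiteObservations:
    """Low-coverage whole-genome sequencing of one segregant.

    Per-SNP depth ~ Poisson(mean_coverage); each read reports the true
    read-space allele flipped with probability ``error_rate``.  Only covered
    sites are stored.
    """
    alleles = np.asarray(alleles)
    if mean_coverage < 0:
        raise ValueError("mean_coverage must be >= 0")
    n = alleles.size
    if mean_coverage == 0:
        empty = np.empty(0, dtype=np.int64)
        return SiteObservations(empty, empty, empty, n)
    depth = rng.poisson(mean_coverage, size=n)
    truth_3s = alleles != BY
    p = np.where(truth_3s, 1.0 - error_rate, error_rate)
    c3s = rng.binomial(depth, p)
    covered = depth > 0
    idx = np.nonzero(covered)[0]
    return SiteObservations(idx, (depth - c3s)[covered], c3s[covered], n)
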