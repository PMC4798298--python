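"""Genome maps, backcross designs, and the Haldane map function.

The package works on a haploid yeast genome described by a :class:`GenomeMap`:
an ordered set of chromosomes, each carrying biallelic SNPs that differentiate
the BY (lab) and 3S (clinical) parental strains.  Physical distance is
converted to genetic distance at a constant rate (default 3,300 bp per
centimorgan) and to recombination fractions through the Haldane map function.

A :class:`CrossDesign` describes one backcross: a focal recombinant parent
(given as a per-SNP allele vector over {BY, 3S, MUT}) mated to one of the two
parental strains.  SNPs where the focal parent matches the recurrent parent
are fixed in every offspring; the remaining SNPs segregate 1:1.  The third
allele MUT models the ira2 frameshift (ira2Δ2933), which arose on the 3S
chromosome and is therefore indistinguishable from 3S in short-read data
("read space") while remaining a distinct allele for the genotype rules.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

# Integer allele codes used throughout the package.
BY, S3, MUT = 0, 1, 2
ALLELE_CODES = {"BY": BY, "3S": S3, "MUT": MUT}
ALLELE_NAMES = {BY: "BY", S3: "3S", MUT: "MUT"}

#: Read-space collapse: ira2Δ2933 sits on a 3S chromosome, so its reads carry
#: the 3S allele at every flanking SNP and the site itself aligns as 3S.
READ_CODE = {BY: BY, S3: S3, MUT: S3}

ROMAN = [
    "I", "II", "III", "IV", "V", "VI", "VII", "VIII",
    "IX", "X", "XI", "XII", "XIII", "XIV", "XV", "XVI",
]


def haldane(d_cm):
    """Recombination fraction for a genetic distance in centimorgans.

    r(d) = (1 - exp(-2 d/100)) / 2.  Vectorised; r(0) = 0 and r -> 1/2 as
    d -> infinity.
    """
    return 0.5 * (1.0 - np.exp(-2.0 * np.asarray(d_cm, dtype=float) / 100.0))


@dataclass(frozen=True)
class GenomeMap:
    """SNP marker map over a set of chromosomes.

    Parameters
    ----------
    chromosomes
        Sequence of ``(name, length_bp)`` pairs, in genome order.
    snp_chrom
        Chromosome index (into ``chromosomes``) of each SNP.  SNPs must be
        grouped by chromosome in genome order.
    snp_pos
        0-based position of each SNP, strictly increasing within chromosome
        and within ``[0, length)``.
    map_scale
        Base pairs per centimorgan (default 3,300).
    """

    chromosomes: tuple
    snp_chrom: np.ndarray
    snp_pos: np.ndarray
    map_scale: float = 3300.0

    def __post_init__(self):
        object.__setattr__(self, "chromosomes", tuple((str(n), int(L)) for n, L in self.chromosomes))
        object.__setattr__(self, "snp_chrom", np.asarray(self.snp_chrom, dtype=np.int64))
        object.__setattr__(self, "snp_pos", np.asarray(self.snp_pos, dtype=np.int64))
        if self.map_scale <= 0:
            raise ValueError("map_scale must be positive")
        if self.snp_chrom.shape != self.snp_pos.shape:
            raise ValueError("snp_chrom and snp_pos must have the same length")
        if self.n_snps == 0:
            raise ValueError("a GenomeMap needs at least one SNP")
        if np.any(np.diff(self.snp_chrom) < 0):
            raise ValueError("SNPs must be grouped by chromosome in genome order")
        for ci, (name, length) in enumerate(self.chromosomes):
            if length <= 0:
                raise ValueError(f"chromosome {name} has non-positive length")
            pos = self.snp_pos[self.snp_chrom == ci]
            if pos.size and (np.any(np.diff(pos) <= 0) or pos[0] < 0 or pos[-1] >= length):
                raise ValueError(f"SNP positions on {name} must be strictly increasing within [0, {length})")

    @property
    def n_snps(self) -> int:
        return int(self.snp_pos.size)

    @property
    def n_chromosomes(self) -> int:
        return len(self.chromosomes)

    @property
    def chrom_names(self):
        return [n for n, _ in self.chromosomes]

    def chrom_length(self, ci: int) -> int:
        return self.chromosomes[ci][1]

    def chrom_slice(self, ci: int) -> slice:
        """Index slice of the SNPs on chromosome ``ci``."""
        lo, hi = np.searchsorted(self.snp_chrom, [ci, ci + 1])
        return slice(int(lo), int(hi))

    def snp_index(self, chrom_name: str, pos0: int) -> int:
        ci = self.chrom_names.index(chrom_name)
        sl = self.chrom_slice(ci)
        j = np.searchsorted(self.snp_pos[sl], pos0)
        if j == sl.stop - sl.start or self.snp_pos[sl][j] != pos0:
            raise KeyError(f"no SNP at {chrom_name}:{pos0}")
        return sl.start + int(j)

    def recomb_fractions(self, ci: int) -> np.ndarray:
        """Haldane recombination fraction between adjacent SNPs on ``ci``."""
        sl = self.chrom_slice(ci)
        d_bp = np.diff(self.snp_pos[sl])
        return haldane(d_bp / self.map_scale)


# ---------------------------------------------------------------------------
# Desk-scale default map

#: Default chromosome lengths in kb (16 chromosomes, 50-150 kb).
_DEFAULT_LENGTHS_KB = (132, 78, 105, 150, 92, 61, 121, 84, 139, 70, 96, 147, 88, 56, 128, 50)

#: Chromosome (roman numeral) carrying each named causal locus.  Each locus
#: sits on its own chromosome; the unresolved Chromosome XII locus keeps its
#: chromosome as its name.
CAUSAL_CHROMOSOME = {
    "SFL1": "II",
    "END3": "IV",
    "FLO8": "V",
    "MGA1": "VII",
    "TRR1": "VIII",
    "FLO11": "IX",
    "XII": "XII",
    "MSS11": "XIII",
    "IRA2": "XV",
}

#: Inferred genotype of the focal rough recombinant parent at the causal loci.
#: It reproduces the observed segregation pattern: FLO8/FLO11/IRA2/TRR1
#: segregate in the BY backcross, END3/MGA1/MSS11/SFL1/XII/IRA2 in the 3S
#: backcross.
DEFAULT_FOCAL_GENOTYPE = {
    "END3": "BY",
    "FLO8": "3S",
    "FLO11": "3S",
    "IRA2": "MUT",
    "MGA1": "BY",
    "MSS11": "BY",
    "SFL1": "BY",
    "TRR1": "3S",
    "XII": "BY",
}


def build_default_map(snp_spacing: int = 800, map_scale: float = 3300.0) -> GenomeMap:
    """Desk-scale 16-chromosome map: ~2,000 evenly spaced SNPs over ~1.6 Mb.

    Chromosome names follow yeast roman-numeral convention.  SNPs sit at
    ``spacing/2 + k*spacing``; at the default spacing of 800 bp adjacent SNPs
    are ~0.24 cM apart.  Scales up to denser maps by shrinking ``snp_spacing``.
    """
    chroms = [(f"chr{ROMAN[i]}", _DEFAULT_LENGTHS_KB[i] * 1000) for i in range(16)]
    chrom_idx, pos = [], []
    for ci, (_, length) in enumerate(chroms):
        p = np.arange(snp_spacing // 2, length, snp_spacing, dtype=np.int64)
        chrom_idx.append(np.full(p.size, ci, dtype=np.int64))
        pos.append(p)
    return GenomeMap(tuple(chroms), np.concatenate(chrom_idx), np.concatenate(pos), map_scale)


@dataclass(frozen=True)
class CrossDesign:
    """One backcross: focal recombinant parent x recurrent parental strain.

    ``focal_parent`` gives the focal parent's allele code at every SNP of
    ``genome_map``; ``backcross_to`` names the recurrent parent.  ``locus_snp``
    maps named causal loci to their SNP index, so simulated genomes can be
    summarised as multi-locus genotype vectors.
    """

    genome_map: GenomeMap
    focal_parent: np.ndarray
    backcross_to: str
    locus_snp: dict = field(default_factory=dict)

    def __post_init__(self):
        object.__setattr__(self, "focal_parent", np.asarray(self.focal_parent, dtype=np.int8))
        if self.backcross_to not in ("BY", "3S"):
            raise ValueError("backcross_to must be 'BY' or '3S'")
        if self.focal_parent.size != self.genome_map.n_snps:
            raise ValueError("focal_parent must cover every SNP of the map")
        if not np.isin(self.focal_parent, [BY, S3, MUT]).all():
            raise ValueError("focal_parent alleles must be BY/3S/MUT codes")

    @property
    def recurrent_code(self) -> int:
        return ALLELE_CODES[self.backcross_to]

    @property
    def segregating(self) -> np.ndarray:
        """True where offspring genotype varies (focal != recurrent allele)."""
        return self.focal_parent != self.recurrent_code

    @property
    def read_segregating(self) -> np.ndarray:
        """True where the segregation is visible to short reads.

        MUT reads as 3S, so a MUT/3S site (IRA2 in the 3S backcross) is fixed
        in read space even though it genuinely segregates.
        """
        focal_reads = np.array([READ_CODE[BY], READ_CODE[S3], READ_CODE[MUT]], dtype=np.int8)[self.focal_parent]
        return focal_reads != READ_CODE[self.recurrent_code]

    def fixed_read_alleles(self) -> np.ndarray:
        """Read-space allele (BY/3S code) at every SNP, valid where not read-segregating."""
        return np.full(self.genome_map.n_snps, READ_CODE[self.recurrent_code], dtype=np.int8)

    def genotype_of(self, alleles: np.ndarray) -> dict:
        """Multi-locus genotype vector (locus name -> allele string) of one genome."""
        return {name: ALLELE_NAMES[int(alleles[snp])] for name, snp in self.locus_snp.items()}

    def to_locus_design(self):
        """Per-locus fixed/segregating summary consumed by the rule engine."""
        from .rules import LocusDesign

        statuses = {}
        rec = self.recurrent_code
        for name, snp in self.locus_snp.items():
            focal = int(self.focal_parent[snp])
            if focal == rec:
                statuses[name] = ("fixed", ALLELE_NAMES[focal])
            else:
                statuses[name] = ("segregating", frozenset({ALLELE_NAMES[focal], ALLELE_NAMES[rec]}))
        return LocusDesign(statuses)


def default_cross_design(
    genome_map: GenomeMap,
    backcross_to: str,
    focal_genotype: dict | None = None,
    causal_chromosome: dict | None = None,
) -> CrossDesign:
    """Backcross design with the default focal-parent mosaic.

    Chromosomes carrying a causal locus take that locus' parental background
    throughout (the IRA2 chromosome is 3S with MUT at the IRA2 SNP itself);
    chromosomes without a causal locus are half BY, half 3S, so each backcross
    fixes roughly half the genome and partial chromosomes exercise the
    segregating-region subsetting.
    """
    focal_genotype = dict(DEFAULT_FOCAL_GENOTYPE if focal_genotype is None else focal_genotype)
    causal_chromosome = dict(CAUSAL_CHROMOSOME if causal_chromosome is None else causal_chromosome)
    names = genome_map.chrom_names
    by_chrom = {}
    for locus, roman in causal_chromosome.items():
        cname = f"chr{roman}" if not roman.startswith("chr") else roman
        if cname not in names:
            raise ValueError(f"causal locus {locus} assigned to unknown chromosome {cname}")
        by_chrom[names.index(cname)] = locus

    focal = np.empty(genome_map.n_snps, dtype=np.int8)
    locus_snp = {}
    for ci in range(genome_map.n_chromosomes):
        sl = genome_map.chrom_slice(ci)
        pos = genome_map.snp_pos[sl]
        if ci in by_chrom:
            locus = by_chrom[ci]
            allele = ALLELE_CODES[focal_genotype[locus]]
            background = S3 if allele == MUT else allele
            focal[sl] = background
            mid = sl.start + pos.size // 2
            locus_snp[locus] = mid
            if allele == MUT:
                focal[mid] = MUT
        else:
            half = genome_map.chrom_length(ci) // 2
            focal[sl] = np.where(pos < half, BY, S3)
    return CrossDesign(genome_map, focal, backcross_to, locus_snp)
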