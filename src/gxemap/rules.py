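"""Multi-locus genotype -> temperature-sensitivity rule engine.

Expression of the rough colony phenotype in BYx3S ira2Δ2933 segregants is
governed by combinations of alleles at eight named loci (END3, FLO8, FLO11,
IRA2, MGA1, MSS11, SFL1, TRR1) plus an unresolved locus on Chromosome XII.
Each :class:`GenotypeRule` maps a required allele combination to the set of
temperatures (subset of {21, 30, 37} °C) at which the combination permits the
phenotype.  A genotype expresses the union of the temperature sets of every
rule it satisfies; the empty union means smooth (no expression) at all
temperatures.

The packaged default :class:`RuleSet` encodes the five predominant multi-locus
genotypes: two highly sensitive (HS-a, HS-b; rough at 21 °C only), two
moderately sensitive (MS-a, MS-b; rough at 21 and 30 °C), and one
non-sensitive (NS; rough at all three temperatures).  FLO8^3S and the ira2
frameshift (allele "MUT") are required by every rule and are therefore
general requirements for the trait rather than temperature modifiers.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass
from importlib import resources

import numpy as np

TEMPERATURES = (21, 30, 37)
ALLELES = ("BY", "3S", "MUT")

#: Temperature set -> sensitivity class under the default rules.
CLASS_BY_TEMPS = {
    frozenset(): "SMOOTH",
    frozenset({21}): "HS",
    frozenset({21, 30}): "MS",
    frozenset({21, 30, 37}): "NS",
}

#: Inverse of CLASS_BY_TEMPS, used by the phenotype-score simulator.
TEMPS_BY_CLASS = {v: set(k) for k, v in CLASS_BY_TEMPS.items()}


class MissingLocusError(KeyError):
    """A genotype vector lacks a locus named by the rule set."""

    def __init__(self, locus):
        super().__init__(locus)
        self.locus = locus

    def __str__(self):
        return f"genotype vector is missing required locus {self.locus!r}"


@dataclass(frozen=True)
class Locus:
    """A named locus with its map location (position is 1-based bp)."""

    name: str
    chromosome: str
    position: int

    def __post_init__(self):
        if self.position < 1:
            raise ValueError("position must be >= 1 (1-based)")


@dataclass(frozen=True)
class GenotypeRule:
    """Required alleles at named loci -> permissive temperature set."""

    name: str
    requirements: dict
    temperatures: frozenset

    def __post_init__(self):
        object.__setattr__(self, "requirements", dict(self.requirements))
        object.__setattr__(self, "temperatures", frozenset(int(t) for t in self.temperatures))
        if not self.requirements:
            raise ValueError(f"rule {self.name}: requirements must be non-empty")
        if not self.temperatures or not self.temperatures <= set(TEMPERATURES):
            raise ValueError(f"rule {self.name}: temperatures must be a non-empty subset of {TEMPERATURES}")
        for locus, allele in self.requirements.items():
            if allele not in ALLELES:
                raise ValueError(f"rule {self.name}: unknown allele {allele!r} at {locus}")

    def satisfied_by(self, genotype: dict) -> bool:
        """True iff ``genotype`` carries every required allele.

        Raises :class:`MissingLocusError` if a required locus is absent.
        """
        for locus, allele in self.requirements.items():
            if locus not in genotype:
                raise MissingLocusError(locus)
            if genotype[locus] != allele:
                return False
        return True


@dataclass(frozen=True)
class RuleSet:
    """An ordered collection of uniquely named genotype rules."""

    rules: tuple

    def __post_init__(self):
        object.__setattr__(self, "rules", tuple(self.rules))
        names = [r.name for r in self.rules]
        if len(set(names)) != len(names):
            raise ValueError("rule names must be unique")

    def __iter__(self):
        return iter(self.rules)

    def __len__(self):
        return len(self.rules)

    def __getitem__(self, name: str) -> GenotypeRule:
        for r in self.rules:
            if r.name == name:
                return r
        raise KeyError(name)

    @property
    def loci(self) -> set:
        return set().union(*(r.requirements.keys() for r in self.rules))

    def validate_core_pair(self, core=(("FLO8", "3S"), ("IRA2", "MUT"))):
        """Assert every rule requires the generally required pair (FLO8^3S, ira2Δ2933)."""
        for rule in self.rules:
            for locus, allele in core:
                if rule.requirements.get(locus) != allele:
                    raise ValueError(f"rule {rule.name} does not require {locus}^{allele}")

    # -- serialization ------------------------------------------------------

    def to_json(self) -> str:
        doc = [
            {"name": r.name, "requirements": r.requirements, "temperatures": sorted(r.temperatures)}
            for r in self.rules
        ]
        return json.dumps(doc, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "RuleSet":
        doc = json.loads(text)
        return cls(tuple(GenotypeRule(d["name"], d["requirements"], frozenset(d["temperatures"])) for d in doc))

    @classmethod
    def default(cls) -> "RuleSet":
        """The packaged five-genotype rule set (validated for the core pair)."""
        text = resources.files("gxemap.data").joinpath("default_rules.json").read_text()
        rs = cls.from_json(text)
        rs.validate_core_pair()
        return rs


# ---------------------------------------------------------------------------
# Rule evaluation


def expressed_temperatures(genotype: dict, ruleset: RuleSet) -> set:
    """Temperatures at which ``genotype`` expresses the rough phenotype.

    Union of the permissive temperature sets over every satisfied rule; the
    empty set means the genotype is smooth at all temperatures.  Overlapping
    rules combine by union, which for the nested default rules is equivalent
    to the most permissive satisfied genotype winning.
    """
    temps: set = set()
    for rule in ruleset:
        if rule.satisfied_by(genotype):
            temps |= rule.temperatures
    return temps


def classify(genotype: dict, ruleset: RuleSet) -> str:
    """Temperature-sensitivity class (HS / MS / NS / SMOOTH) of a genotype.

    Under the default rule set the union of satisfied temperature sets is
    always one of {}, {21}, {21,30}, {21,30,37}; any other pattern indicates
    an inconsistent custom rule set and raises ``ValueError``.
    """
    temps = frozenset(expressed_temperatures(genotype, ruleset))
    try:
        return CLASS_BY_TEMPS[temps]
    except KeyError:
        raise ValueError(f"temperature pattern {sorted(temps)} has no sensitivity class") from None


def identify_temperature_modifiers(ruleset: RuleSet) -> set:
    """Loci whose alleles modulate temperature sensitivity.

    A locus required with one identical allele by *every* rule (like FLO8^3S
    and IRA2^MUT in the default set) is generally required for the trait and
    is excluded; every other locus that appears in at least one rule's
    requirements is an environmentally responsive modifier.
    """
    if len(ruleset) == 0:
        raise ValueError("rule set is empty")
    modifiers = set()
    for locus in ruleset.loci:
        alleles = {r.requirements.get(locus) for r in ruleset}
        if len(alleles) == 1 and None not in alleles:
            continue  # generally required with a uniform allele
        modifiers.add(locus)
    return modifiers


# ---------------------------------------------------------------------------
# Mendelian expectations


@dataclass(frozen=True)
class LocusDesign:
    """Per-locus segregation status of a cross, for Mendelian expectations.

    ``statuses`` maps locus name to either ``("fixed", allele)`` or
    ``("segregating", {allele_a, allele_b})``.  Obtainable from a genome-scale
    :class:`~gxemap.genome.CrossDesign` via ``to_locus_design()``, or built
    directly (e.g. an intercross where every locus segregates).
    """

    statuses: dict

    def __post_init__(self):
        object.__setattr__(self, "statuses", dict(self.statuses))
        for locus, (kind, payload) in self.statuses.items():
            if kind not in ("fixed", "segregating"):
                raise ValueError(f"{locus}: unknown status kind {kind!r}")
            if kind == "segregating" and len(payload) != 2:
                raise ValueError(f"{locus}: a segregating locus needs exactly two alleles")

    @classmethod
    def intercross(cls, loci, mutation_locus: str = "IRA2") -> "LocusDesign":
        """Design in which every named locus segregates 1:1.

        Ordinary loci segregate BY/3S; ``mutation_locus`` segregates MUT/BY
        (the frameshift arose on one chromosome of a BY/3S diploid).
        """
        statuses = {}
        for locus in loci:
            pair = {"MUT", "BY"} if locus == mutation_locus else {"BY", "3S"}
            statuses[locus] = ("segregating", frozenset(pair))
        return cls(statuses)


def expected_frequency(rule: GenotypeRule, design: LocusDesign) -> float:
    """Mendelian probability that a random offspring satisfies ``rule``.

    Product over the rule's required loci: 1/2 if the locus segregates and the
    required allele is one of its two alleles, 1 if it is fixed for the
    required allele, 0 otherwise.  A genotype requiring one more segregating
    allele than another is expected half as often.
    """
    p = 1.0
    for locus, allele in rule.requirements.items():
        if locus not in design.statuses:
            raise KeyError(f"locus {locus!r} absent from the cross design")
        kind, payload = design.statuses[locus]
        if kind == "fixed":
            if payload != allele:
                return 0.0
        else:
            if allele not in payload:
                return 0.0
            p *= 0.5
    return p


def enumerate_genotypes(design: LocusDesign):
    """All equally likely genotype vectors of a design (brute-force oracle).

    Fixed loci contribute their allele; each segregating locus contributes
    both alleles, yielding 2**k genotypes for k segregating loci.  Intended
    for small k.
    """
    names = list(design.statuses)
    choices = []
    for locus in names:
        kind, payload = design.statuses[locus]
        choices.append([payload] if kind == "fixed" else sorted(payload))
    for combo in itertools.product(*choices):
        yield dict(zip(names, combo))


def sample_genotypes(design: LocusDesign, n: int, rng: np.random.Generator):
    """Draw ``n`` independent Mendelian genotype vectors from a design."""
    names = list(design.statuses)
    fixed, pairs = {}, {}
    for locus in names:
        kind, payload = design.statuses[locus]
        if kind == "fixed":
            fixed[locus] = payload
        else:
            pairs[locus] = sorted(payload)
    draws = {locus: rng.integers(0, 2, size=n) for locus in pairs}
    out = []
    for i in range(n):
        g = dict(fixed)
        for locus, pair in pairs.items():
            g[locus] = pair[draws[locus][i]]
        out.append(g)
    return out
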