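"""Haplotype inference for low-coverage single segregants.

Each backcross offspring is a mosaic of the two parental haplotypes.  With
~1X sequencing most SNPs carry zero or one read, so per-site genotyping is
hopeless; linkage rescues it.  A two-state hidden Markov model over the
read-space alleles {BY, 3S} walks each chromosome's segregating SNPs:
transitions between adjacent SNPs follow the Haldane recombination fraction
of their distance, and a read emits the true allele with probability
``1 - error_rate``.  The hard state path comes from Viterbi (ties broken
toward the previous state, preserving segments) and per-SNP confidence from
the forward-backward posteriors.  Fixed regions of the backcross are filled
in from the design with posterior 1.

Individuals are excluded up front when their mean coverage falls below the
1.02X threshold, and can be excluded after decoding if they carry the
wild-type (recurrent) allele at the IRA2 SNP.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genome import BY, S3, CrossDesign, GenomeMap
from .simulate import SiteObservations

MISSING = -1  # genotype-matrix code for a low-confidence call


@dataclass(frozen=True)
class HaplotypeCall:
    """Per-SNP read-space states (BY/3S codes) with per-state posteriors.

    ``posterior`` is the probability of the called state (in [0.5, 1] at
    decoded SNPs; exactly 1 in design-fixed regions).  ``decoded`` marks the
    SNPs that went through the HMM rather than being filled from the design.
    """

    states: np.ndarray
    posterior: np.ndarray
    decoded: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "states", np.asarray(self.states, dtype=np.int8))
        object.__setattr__(self, "posterior", np.asarray(self.posterior, dtype=float))
        object.__setattr__(self, "decoded", np.asarray(self.decoded, dtype=bool))


def coverage_filter(observations: SiteObservations, min_coverage: float = 1.02) -> bool:
    """Keep an individual iff its mean per-site coverage is >= ``min_coverage``."""
    return observations.mean_coverage >= min_coverage


def _viterbi_2state(log_emit: np.ndarray, log_stay: np.ndarray, log_switch: np.ndarray) -> np.ndarray:
    """Max-probability path for a 2-state chain; ties prefer staying put."""
    T = log_emit.shape[0]
    delta = np.log(0.5) + log_emit[0]
    back = np.zeros((T, 2), dtype=np.int8)
    for t in range(1, T):
        for j in (0, 1):
            stay = delta[j] + log_stay[t - 1]
            switch = delta[1 - j] + log_switch[t - 1]
            # ">=" keeps the previous state on ties, preserving segments
            back[t, j] = j if stay >= switch else 1 - j
        new0 = max(delta[0] + log_stay[t - 1], delta[1] + log_switch[t - 1])
        new1 = max(delta[1] + log_stay[t - 1], delta[0] + log_switch[t - 1])
        delta = np.array([new0, new1]) + log_emit[t]
    path = np.empty(T, dtype=np.int8)
    path[-1] = 0 if delta[0] >= delta[1] else 1
    for t in range(T - 1, 0, -1):
        path[t - 1] = back[t, path[t]]
    return path


def _forward_backward_2state(log_emit: np.ndarray, log_stay: np.ndarray, log_switch: np.ndarray) -> np.ndarray:
    """Posterior state probabilities, normalised exactly at every SNP."""
    T = log_emit.shape[0]
    fwd = np.empty((T, 2))
    bwd = np.empty((T, 2))
    fwd[0] = np.log(0.5) + log_emit[0]
    for t in range(1, T):
        fwd[t, 0] = np.logaddexp(fwd[t - 1, 0] + log_stay[t - 1], fwd[t - 1, 1] + log_switch[t - 1])
        fwd[t, 1] = np.logaddexp(fwd[t - 1, 1] + log_stay[t - 1], fwd[t - 1, 0] + log_switch[t - 1])
        fwd[t] += log_emit[t]
    bwd[-1] = 0.0
    for t in range(T - 2, -1, -1):
        e = bwd[t + 1] + log_emit[t + 1]
        bwd[t, 0] = np.logaddexp(e[0] + log_stay[t], e[1] + log_switch[t])
        bwd[t, 1] = np.logaddexp(e[1] + log_stay[t], e[0] + log_switch[t])
    post = fwd + bwd
    post -= np.logaddexp(post[:, 0], post[:, 1])[:, None]
    return np.exp(post)


def genotype_hmm(
    observations: SiteObservations,
    genome_map: GenomeMap,
    design: CrossDesign,
    error_rate: float = 0.005,
) -> HaplotypeCall:
    """Decode one segregant's parental-origin states from sparse read counts.

    Only read-segregating SNPs of the backcross are decoded; the rest are
    filled from the design.  Raises ``ValueError`` when the design leaves
    nothing to decode.
    """
    if not (0 < error_rate < 0.5):
        raise ValueError("error_rate must be in (0, 0.5)")
    seg = design.read_segregating
    if not seg.any():
        raise ValueError("design has no read-segregating SNPs to decode")
    n = genome_map.n_snps
    c_by = np.zeros(n)
    c_3s = np.zeros(n)
    c_by[observations.snp_index] = observations.count_by
    c_3s[observations.snp_index] = observations.count_3s

    states = design.fixed_read_alleles()
    posterior = np.ones(n)
    log_e, log_1e = np.log(error_rate), np.log1p(-error_rate)

    for ci in range(genome_map.n_chromosomes):
        sl = genome_map.chrom_slice(ci)
        idx = np.arange(sl.start, sl.stop)[seg[sl]]
        if idx.size == 0:
            continue
        # binomial coefficients cancel between the two states
        log_emit = np.column_stack(
            [
                c_by[idx] * log_1e + c_3s[idx] * log_e,  # state BY
                c_by[idx] * log_e + c_3s[idx] * log_1e,  # state 3S
            ]
        )
        d_cm = np.diff(genome_map.snp_pos[idx]) / genome_map.map_scale
        from .genome import haldane

        r = haldane(d_cm)
        log_switch = np.log(np.maximum(r, 1e-300))
        log_stay = np.log1p(-r)
        path = _viterbi_2state(log_emit, log_stay, log_switch)
        post = _forward_backward_2state(log_emit, log_stay, log_switch)
        p_path = post[np.arange(idx.size), path]
        # The Viterbi path occasionally crosses isolated SNPs whose marginal
        # posterior favours the other state; report the marginal-majority
        # state there so the called-state confidence is always >= 1/2.
        flip = p_path < 0.5
        path = np.where(flip, 1 - path, path)
        p_path = np.where(flip, 1.0 - p_path, p_path)
        states[idx] = np.where(path == 0, BY, S3)
        posterior[idx] = p_path
    return HaplotypeCall(states, posterior, seg.copy())


def carries_wildtype_ira2(call: HaplotypeCall, design: CrossDesign, locus: str = "IRA2") -> bool:
    """True when the decoded state at the IRA2 SNP is the wild-type allele.

    Only meaningful in the backcross where the mutation is read-visible (the
    BY backcross, where MUT reads as 3S against a BY recurrent allele); in
    the other backcross the site is read-fixed and the answer is always
    False.
    """
    snp = design.locus_snp.get(locus)
    if snp is None:
        raise KeyError(f"design does not place locus {locus!r}")
    if not design.read_segregating[snp]:
        return False
    return int(call.states[snp]) == design.recurrent_code


def genotype_matrix(calls, design: CrossDesign, posterior_min: float = 0.9) -> np.ndarray:
    """Stack haplotype calls into a (segregating SNPs x individuals) matrix.

    Values are BY/3S codes with ``MISSING`` (-1) where the posterior of the
    called state falls below ``posterior_min``.
    """
    seg = design.read_segregating
    cols = []
    for call in calls:
        col = call.states[seg].astype(np.int8)
        col[call.posterior[seg] < posterior_min] = MISSING
        cols.append(col)
    return np.column_stack(cols) if cols else np.empty((int(seg.sum()), 0), dtype=np.int8)
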