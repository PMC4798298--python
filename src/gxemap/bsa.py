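"""Bulk segregant analysis: allele-frequency tracks, LOD scan, locus calls.

Class-specific pools of phenotype-selected segregants are sequenced; causal
loci show up as allele-frequency skews away from the 1:1 backcross
expectation.  The scan statistic is a binned binomial LOD: reads are
aggregated into 100-bp bins, pooled around each evaluation point under a
Gaussian kernel (default scale 10 cM = 33,000 bp at 3,300 bp/cM), and scored
as log10 of the binomial likelihood ratio of the local MLE frequency against
the null p = 0.5.  Pooled counts are capped at twice the number of pooled
individuals, since a finite pool carries at most two effective observations
per member no matter how deep it is sequenced.

Loci are called from contiguous runs of bins with LOD >= 5 spanning >= 20 kb,
one call at the run's peak, with a support interval delimited by a 2-LOD drop
from the peak.

`BulkSegregantScan` wraps the pipeline in a model object whose ``fit()``
returns a :class:`BulkSegregantResults` carrying the tracks and calls.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import xlogy

from .genome import ALLELE_NAMES, BY, S3, CrossDesign, GenomeMap
from .simulate import PoolCounts

_LN10 = np.log(10.0)


@dataclass(frozen=True)
class AlleleFrequencyTrack:
    """Per-SNP 3S-allele frequency; NaN marks zero-depth (missing) SNPs."""

    snp_index: np.ndarray
    frequency: np.ndarray
    window: int = 1  # smoothing window in SNPs (1 = raw)

    def __post_init__(self):
        object.__setattr__(self, "snp_index", np.asarray(self.snp_index, dtype=np.int64))
        object.__setattr__(self, "frequency", np.asarray(self.frequency, dtype=float))
        if self.snp_index.shape != self.frequency.shape:
            raise ValueError("snp_index and frequency must align")


@dataclass(frozen=True)
class LodTrack:
    """Binned LOD scan: per bin, pooled evidence against allele frequency 0.5."""

    chrom: np.ndarray  # chromosome index per bin
    bin_start: np.ndarray  # 0-based bp of bin start
    lod: np.ndarray
    enriched: np.ndarray  # +1 (3S), -1 (BY), 0 (no data / exactly 0.5)
    eff_depth: np.ndarray  # capped pooled depth behind each LOD value
    bin_size: int


@dataclass(frozen=True)
class LocusCall:
    """A significant locus: peak, strength, direction and 2-LOD support interval."""

    chromosome: str
    peak: int  # 0-based bp
    max_lod: float
    enriched_parent: str  # "BY" or "3S"
    start: int  # support interval, 0-based half-open
    end: int


def subset_segregating(counts: PoolCounts, design: CrossDesign) -> PoolCounts:
    """Drop SNPs fixed in this backcross (read space); keeps index mapping."""
    idx = counts.indices()
    keep = design.read_segregating[idx]
    return PoolCounts(counts.count_by[keep], counts.count_3s[keep], idx[keep])


def estimate_frequencies(counts: PoolCounts) -> AlleleFrequencyTrack:
    """Raw per-SNP 3S frequency = count_3S / depth, NaN where depth is zero."""
    depth = counts.depth.astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        f = np.where(depth > 0, counts.count_3s / depth, np.nan)
    return AlleleFrequencyTrack(counts.indices(), f)


def _smooth_within_groups(values: np.ndarray, groups: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average per group, truncated at ends, NaN-skipping."""
    s = pd.Series(values)
    return (
        s.groupby(groups)
        .transform(lambda x: x.rolling(window, center=True, min_periods=1).mean())
        .to_numpy()
    )


def smooth_track(track: AlleleFrequencyTrack, genome_map: GenomeMap, window: int = 25) -> AlleleFrequencyTrack:
    """Sliding-window mean of the frequency track within chromosomes.

    ``window`` must be odd; windows truncate (never pad) at chromosome ends
    and missing SNPs are excluded from the denominators.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be odd and >= 1")
    groups = genome_map.snp_chrom[track.snp_index]
    return AlleleFrequencyTrack(track.snp_index, _smooth_within_groups(track.frequency, groups, window), window)


def _gaussian_kernel(sigma_bins: float) -> np.ndarray:
    half = int(np.ceil(3 * sigma_bins))
    d = np.arange(-half, half + 1, dtype=float)
    return np.exp(-0.5 * (d / sigma_bins) ** 2)


def lod_scan(
    counts: PoolCounts,
    genome_map: GenomeMap,
    bin_size: int = 100,
    kernel_scale: float = 33000.0,
    depth_cap: float | None = None,
) -> LodTrack:
    """Kernel-pooled binomial LOD along the genome.

    Reads are binned (``bin_size`` bp), pooled under a Gaussian kernel of
    scale ``kernel_scale`` bp around each bin, optionally rescaled so the
    pooled depth never exceeds ``depth_cap`` (use 2x the number of pooled
    individuals), and scored as
    ``LOD = log10 [ p^k (1-p)^(n-k) / 0.5^n ]`` at the local MLE ``p = k/n``.
    The enriched parent is the sign of p - 0.5.
    """
    if counts.n_sites == 0:
        raise ValueError("empty pool counts")
    idx = counts.indices()
    snp_chrom = genome_map.snp_chrom[idx]
    snp_pos = genome_map.snp_pos[idx]
    sigma_bins = kernel_scale / bin_size
    kernel = _gaussian_kernel(sigma_bins)

    chroms, starts, lods, enriched, effd = [], [], [], [], []
    for ci in range(genome_map.n_chromosomes):
        on = snp_chrom == ci
        n_bins = int(np.ceil(genome_map.chrom_length(ci) / bin_size))
        b3s = np.zeros(n_bins)
        bby = np.zeros(n_bins)
        if on.any():
            bins = snp_pos[on] // bin_size
            np.add.at(b3s, bins, counts.count_3s[on])
            np.add.at(bby, bins, counts.count_by[on])
        half = kernel.size // 2
        k3s = np.convolve(b3s, kernel, mode="full")[half : half + n_bins]
        kby = np.convolve(bby, kernel, mode="full")[half : half + n_bins]
        tot = k3s + kby
        if depth_cap is not None:
            with np.errstate(invalid="ignore", divide="ignore"):
                scale = np.where(tot > depth_cap, depth_cap / tot, 1.0)
            k3s, kby, tot = k3s * scale, kby * scale, np.minimum(tot, depth_cap)
        with np.errstate(invalid="ignore", divide="ignore"):
            phat = np.where(tot > 0, k3s / tot, 0.5)
        lod = (xlogy(k3s, phat) + xlogy(kby, 1.0 - phat) - tot * np.log(0.5)) / _LN10
        lod = np.maximum(lod, 0.0)  # clip numerical negatives at the null
        sign = np.sign(phat - 0.5).astype(np.int8)
        sign[tot == 0] = 0
        chroms.append(np.full(n_bins, ci, dtype=np.int64))
        starts.append(np.arange(n_bins, dtype=np.int64) * bin_size)
        lods.append(lod)
        enriched.append(sign)
        effd.append(tot)
    return LodTrack(
        np.concatenate(chroms),
        np.concatenate(starts),
        np.concatenate(lods),
        np.concatenate(enriched),
        np.concatenate(effd),
        bin_size,
    )


def call_loci(
    track: LodTrack,
    threshold: float = 5.0,
    min_span: int = 20000,
    drop: float = 2.0,
    genome_map: GenomeMap | None = None,
) -> list:
    """Significant loci from a LOD track.

    Maximal runs of contiguous bins with LOD >= ``threshold`` and a consistent
    enriched parent are candidate loci; runs spanning less than ``min_span``
    bp are discarded.  Each surviving run yields one call at its (leftmost)
    argmax bin, with a support interval reaching out to the nearest bins, on
    either side within the chromosome, where LOD <= maxLOD - ``drop``
    (chromosome end if the track never drops).
    """
    if threshold <= 0 or min_span <= 0 or drop <= 0:
        raise ValueError("threshold, min_span and drop must be positive")
    calls = []
    for ci in np.unique(track.chrom):
        on = track.chrom == ci
        lod = track.lod[on]
        sign = track.enriched[on]
        start_bp = track.bin_start[on]
        sig = (lod >= threshold) & (sign != 0)
        if not sig.any():
            continue
        # break significant stretches at enriched-parent changes
        boundaries = np.flatnonzero(np.diff(sig.astype(np.int8)) != 0) + 1
        segments = np.split(np.arange(lod.size), boundaries)
        for seg in segments:
            if seg.size == 0 or not sig[seg[0]]:
                continue
            for run in _split_by_sign(seg, sign):
                span = run.size * track.bin_size
                if span < min_span:
                    continue
                peak_local = run[np.argmax(lod[run])]  # np.argmax -> leftmost tie
                max_lod = float(lod[peak_local])
                cutoff = max_lod - drop
                left = peak_local
                while left > 0 and lod[left] > cutoff:
                    left -= 1
                right = peak_local
                while right < lod.size - 1 and lod[right] > cutoff:
                    right += 1
                name = str(ci)
                if genome_map is not None:
                    name = genome_map.chrom_names[int(ci)]
                calls.append(
                    LocusCall(
                        chromosome=name,
                        peak=int(start_bp[peak_local] + track.bin_size // 2),
                        max_lod=max_lod,
                        enriched_parent=ALLELE_NAMES[S3] if sign[peak_local] > 0 else ALLELE_NAMES[BY],
                        start=int(start_bp[left]),
                        end=int(start_bp[right] + track.bin_size),
                    )
                )
    return calls


def _split_by_sign(seg: np.ndarray, sign: np.ndarray):
    """Split an index run wherever the enriched parent flips."""
    cuts = np.flatnonzero(np.diff(sign[seg]) != 0) + 1
    return np.split(seg, cuts)


def loci_frame(calls) -> pd.DataFrame:
    """Locus calls as a DataFrame (coordinates 1-based inclusive, as on disk)."""
    return pd.DataFrame(
        [
            {
                "chromosome": c.chromosome,
                "peak": c.peak + 1,
                "start": c.start + 1,
                "end": c.end,
                "max_lod": round(c.max_lod, 4),
                "enriched_parent": c.enriched_parent,
            }
            for c in calls
        ],
        columns=["chromosome", "peak", "start", "end", "max_lod", "enriched_parent"],
    )


class BulkSegregantScan:
    """Bulk-segregant mapping model for one phenotype-selected pool.

    Parameters
    ----------
    counts
        Pooled read counts (all SNPs, or already subset).
    genome_map
        Marker map the counts are indexed against.
    design
        Optional backcross design; when given, SNPs fixed in the backcross
        are removed before scanning.
    n_individuals
        Number of pooled segregants; sets the effective-depth cap at
        ``2 * n_individuals``.
    """

    def __init__(
        self,
        counts: PoolCounts,
        genome_map: GenomeMap,
        design: CrossDesign | None = None,
        n_individuals: int | None = None,
    ):
        self.counts = counts
        self.genome_map = genome_map
        self.design = design
        self.n_individuals = n_individuals

    def fit(
        self,
        window: int = 25,
        bin_size: int = 100,
        kernel_scale: float = 33000.0,
        threshold: float = 5.0,
        min_span: int = 20000,
        drop: float = 2.0,
    ) -> "BulkSegregantResults":
        counts = self.counts
        if self.design is not None:
            counts = subset_segregating(counts, self.design)
        freq = estimate_frequencies(counts)
        smoothed = smooth_track(freq, self.genome_map, window)
        cap = 2 * self.n_individuals if self.n_individuals else None
        track = lod_scan(counts, self.genome_map, bin_size, kernel_scale, depth_cap=cap)
        calls = call_loci(track, threshold, min_span, drop, genome_map=self.genome_map)
        return BulkSegregantResults(self, counts, freq, smoothed, track, calls, threshold, min_span, drop)


class BulkSegregantResults:
    """Fitted tracks and locus calls of a :class:`BulkSegregantScan`."""

    def __init__(self, model, counts, frequencies, smoothed, lod_track, loci, threshold, min_span, drop):
        self.model = model
        self.counts = counts
        self.frequencies = frequencies
        self.smoothed = smoothed
        self.lod_track = lod_track
        self.loci = loci
        self.threshold = threshold
        self.min_span = min_span
        self.drop = drop

    def loci_frame(self) -> pd.DataFrame:
        return loci_frame(self.loci)

    def summary(self) -> str:
        lines = [
            "Bulk segregant LOD scan",
            "=" * 64,
            f"SNPs scanned:      {self.counts.n_sites}",
            f"Pooled depth/site: {self.counts.depth.mean():.1f}X mean",
            f"Call rule:         LOD >= {self.threshold} over >= {self.min_span} bp, "
            f"{self.drop}-LOD support interval",
            f"Loci called:       {len(self.loci)}",
            "-" * 64,
        ]
        df = self.loci_frame()
        lines.append(df.to_string(index=False) if len(df) else "(no significant loci)")
        return "\n".join(lines)
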