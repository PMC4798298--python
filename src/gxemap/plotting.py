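"""Simple genome-track figures for allele-frequency and LOD scans."""

from __future__ import annotations

import numpy as np


def plot_frequency_track(track, genome_map, ax=None, **kwargs):
    """Scatter the (smoothed) 3S-allele frequency along the genome.

    Chromosomes are concatenated on the x axis with dotted separators; the
    dashed line marks the 0.5 backcross expectation.  Returns the axes.
    """
    ax = _axes(ax)
    offsets = _offsets(genome_map)
    x = offsets[genome_map.snp_chrom[track.snp_index]] + genome_map.snp_pos[track.snp_index]
    ax.plot(x, track.frequency, ".", markersize=2, **kwargs)
    ax.axhline(0.5, linestyle="--", linewidth=0.8, color="grey")
    _chrom_guides(ax, genome_map, offsets)
    ax.set_ylim(-0.02, 1.02)
    ax.set_ylabel("3S allele frequency")
    return ax


def plot_lod_track(track, genome_map, threshold=5.0, ax=None, **kwargs):
    """LOD values along the genome with the calling threshold marked."""
    ax = _axes(ax)
    offsets = _offsets(genome_map)
    x = offsets[track.chrom] + track.bin_start + track.bin_size // 2
    ax.plot(x, track.lod, linewidth=0.8, **kwargs)
    ax.axhline(threshold, linestyle="--", linewidth=0.8, color="red")
    _chrom_guides(ax, genome_map, offsets)
    ax.set_ylabel("LOD")
    return ax


def _axes(ax):
    if ax is None:
        import matplotlib.pyplot as plt

        _, ax = plt.subplots(figsize=(10, 2.5))
    return ax


def _offsets(genome_map):
    lengths = np.array([L for _, L in genome_map.chromosomes], dtype=np.int64)
    return np.concatenate([[0], np.cumsum(lengths)[:-1]])


def _chrom_guides(ax, genome_map, offsets):
    for off in offsets[1:]:
        ax.axvline(off, linestyle=":", linewidth=0.5, color="grey")
    centers = offsets + np.array([L for _, L in genome_map.chromosomes]) / 2
    ax.set_xticks(centers)
    ax.set_xticklabels([n.replace("chr", "") for n in genome_map.chrom_names], fontsize=7)
    ax.set_xlabel("chromosome")
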