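"""Genome-wide histogram figures.

Paired per-chromosome bar histograms of binned variant counts (one series
per genotype) and zygosity-colored histograms of a call set (homozygous vs
heterozygous per bin).  Figures are written with deterministic names, one
grid figure per genome by default or one file per chromosome on request.
"""

from __future__ import annotations

import math
import os
from typing import Mapping, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .footprint import BinnedVariantCounts
from .ploidy import PloidyProfile

__all__ = ["plot_genome_histograms", "plot_ploidy_histograms"]

_SERIES_COLORS = {"WT": "#3b6fb6", "KO": "#c23b3b", "HET": "#5aa469"}


def _chrom_union(groups: Mapping[str, Sequence[BinnedVariantCounts]]) -> list[str]:
    from .variants import _chrom_sort_key

    chroms = {b.chrom for series in groups.values() for b in series}
    return sorted(chroms, key=_chrom_sort_key)


def plot_genome_histograms(
    binned_by_genotype: Mapping[str, Sequence[BinnedVariantCounts]],
    out_dir: str | os.PathLike,
    *,
    basename: str = "genome_histograms",
    per_chromosome: bool = False,
) -> list[str]:
    """Plot per-chromosome variant-count histograms, one bar series per
    genotype label.  Empty chromosomes keep an (empty) panel so the genome
    view stays complete.  Returns the written file paths."""
    if not any(len(v) for v in binned_by_genotype.values()):
        raise ValueError("nothing to plot: all binned lists are empty")
    out_dir = os.fspath(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    chroms = _chrom_union(binned_by_genotype)
    by_label = {
        label: {b.chrom: b for b in series}
        for label, series in binned_by_genotype.items()
    }
    labels = list(binned_by_genotype)

    def draw(ax, chrom: str) -> None:
        width = 0.8 / max(len(labels), 1)
        for li, label in enumerate(labels):
            b = by_label[label].get(chrom)
            if b is None:
                continue
            x = np.arange(b.n_bins) + li * width
            ax.bar(
                x,
                b.counts,
                width=width,
                label=label,
                color=_SERIES_COLORS.get(label),
            )
        ax.set_title(chrom, fontsize=9)
        ax.set_xlabel("bin", fontsize=7)
        ax.tick_params(labelsize=7)

    written = []
    if per_chromosome:
        for chrom in chroms:
            fig, ax = plt.subplots(figsize=(5, 3))
            draw(ax, chrom)
            ax.legend(fontsize=7)
            path = os.path.join(out_dir, f"{basename}_{chrom}.png")
            fig.tight_layout()
            fig.savefig(path, dpi=120)
            plt.close(fig)
            written.append(path)
        return written
    ncols = min(3, len(chroms))
    nrows = math.ceil(len(chroms) / ncols)
    fig, axes = plt.subplots(
        nrows, ncols, figsize=(4 * ncols, 2.6 * nrows), squeeze=False
    )
    for i, chrom in enumerate(chroms):
        draw(axes[i // ncols][i % ncols], chrom)
    for j in range(len(chroms), nrows * ncols):
        axes[j // ncols][j % ncols].axis("off")
    axes[0][0].legend(fontsize=7)
    path = os.path.join(out_dir, f"{basename}.png")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return [path]


def plot_ploidy_histograms(
    profiles: Sequence[PloidyProfile],
    out_dir: str | os.PathLike,
    *,
    basename: str = "ploidy_histograms",
) -> list[str]:
    """Zygosity-colored histograms: homozygous (red) vs heterozygous (blue)
    counts per bin, one panel per chromosome, one grid figure."""
    if not profiles:
        raise ValueError("no ploidy profiles to plot")
    out_dir = os.fspath(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    ncols = min(3, len(profiles))
    nrows = math.ceil(len(profiles) / ncols)
    fig, axes = plt.subplots(
        nrows, ncols, figsize=(4 * ncols, 2.6 * nrows), squeeze=False
    )
    for i, p in enumerate(profiles):
        ax = axes[i // ncols][i % ncols]
        x = np.arange(p.n_bins)
        ax.bar(x - 0.2, p.hom_counts, width=0.4, color="#c23b3b", label="hom")
        ax.bar(x + 0.2, p.het_counts, width=0.4, color="#3b6fb6", label="het")
        ax.set_title(f"{p.sample_id} {p.chrom}", fontsize=9)
        ax.tick_params(labelsize=7)
    for j in range(len(profiles), nrows * ncols):
        axes[j // ncols][j % ncols].axis("off")
    axes[0][0].legend(fontsize=7)
    path = os.path.join(out_dir, f"{basename}.png")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return [path]
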