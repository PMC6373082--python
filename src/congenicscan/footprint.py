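"""Genome-wide binning, trend testing, and congenic-footprint estimation.

Variants are binned per chromosome in fixed windows (default 10 Mb).  For
each chromosome the WT and KO binned counts form a 2 x k contingency table
whose columns are ordered along the chromosome; the Cochran-Armitage test
for trend flags chromosomes where the KO/WT proportion drifts along the
chromosome — the signature of a localized introgressed segment on an
otherwise shared background.  The physical extent of the KO-linked
homozygous variants is converted to centimorgans through a genetic map, and
the number of backcross generations N is estimated from the classical
expectation that the donor segment retained around a selected locus spans
about 200/N cM after N backcross generations.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, NamedTuple, Sequence

import numpy as np
from scipy.stats import norm

from .cohort import KoLinkedSet
from .genmap import GeneticMap
from .ploidy import PloidyClass, classify_ploidy
from .variants import GenotypeCallSet

__all__ = [
    "DEFAULT_BIN_SIZE",
    "BinnedVariantCounts",
    "TrendTable",
    "CochranArmitageResult",
    "TrendTestResult",
    "FootprintInterval",
    "bin_variants",
    "cochran_armitage",
    "flag_chromosomes",
    "estimate_footprint_interval",
    "estimate_backcross_generations",
    "build_footprint_interval",
]

logger = logging.getLogger(__name__)

DEFAULT_BIN_SIZE = 10_000_000


@dataclass
class BinnedVariantCounts:
    """Per-chromosome fixed-width bin counts for one genotype label.

    Bin ``k`` covers the half-open window ``[k*bin_size, (k+1)*bin_size)``
    applied to the 1-based VCF coordinate, i.e. position ``pos`` falls in
    bin ``pos // bin_size``.  ``sum(counts)`` equals the chromosome's
    variant count.
    """

    chrom: str
    bin_size: int
    counts: list[int]
    label: str

    @property
    def n_bins(self) -> int:
        return len(self.counts)

    @property
    def total(self) -> int:
        return int(sum(self.counts))

    def bin_start(self, i: int) -> int:
        """Start of bin i on the 1-based coordinate axis."""
        return i * self.bin_size

    def bin_midpoints(self) -> np.ndarray:
        return (np.arange(self.n_bins) + 0.5) * self.bin_size


def bin_variants(
    callset: GenotypeCallSet,
    bin_size: int = DEFAULT_BIN_SIZE,
) -> list[BinnedVariantCounts]:
    """Bin a call set's variant calls (het/hom_alt) per chromosome.

    Returns one :class:`BinnedVariantCounts` per chromosome present, sorted
    by chromosome name (numeric-aware); an empty set yields an empty list.
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be > 0")
    from .variants import _chrom_sort_key

    per_chrom: dict[str, list[int]] = {}
    for call in callset.variant_calls():
        per_chrom.setdefault(call.key.chrom, []).append(call.key.pos)
    out = []
    for chrom in sorted(per_chrom, key=_chrom_sort_key):
        positions = np.asarray(per_chrom[chrom])
        idx = positions // bin_size
        counts = np.bincount(idx).tolist()
        out.append(BinnedVariantCounts(chrom, bin_size, counts, callset.label))
    return out


@dataclass
class TrendTable:
    """A 2 x k contingency table with ordered numeric column scores."""

    row_ko: np.ndarray
    row_wt: np.ndarray
    scores: np.ndarray

    def __post_init__(self) -> None:
        self.row_ko = np.asarray(self.row_ko, float)
        self.row_wt = np.asarray(self.row_wt, float)
        self.scores = np.asarray(self.scores, float)
        if not (len(self.row_ko) == len(self.row_wt) == len(self.scores)):
            raise ValueError("rows and scores must have equal length")
        if len(self.scores) == 0:
            raise ValueError("table must have at least one column")
        if np.any(self.row_ko < 0) or np.any(self.row_wt < 0):
            raise ValueError("counts must be non-negative")


class CochranArmitageResult(NamedTuple):
    z: float
    p_value: float
    degenerate: bool


def cochran_armitage(table: TrendTable) -> CochranArmitageResult:
    """Cochran-Armitage test for linear trend in a 2 x k table.

    With column totals ``c_i = n1_i + n2_i``, row totals ``R1``, ``R2``,
    grand total ``N`` and scores ``t_i``::

        T      = sum_i t_i * (n1_i - c_i * R1 / N)
        Var(T) = (R1 * R2 / N^2) * (sum_i t_i^2 c_i - (sum_i t_i c_i)^2 / N)
        z      = T / sqrt(Var(T));  p = two-sided standard-normal tail

    Degenerate tables (one empty row, or all mass in one column) have
    Var(T) = 0 and are reported as z = 0, p = 1 with ``degenerate=True``.
    The statistic is invariant under positive affine transformation of the
    scores and changes sign when the rows are swapped.
    """
    n1, n2, t = table.row_ko, table.row_wt, table.scores
    c = n1 + n2
    r1, r2 = n1.sum(), n2.sum()
    n = r1 + r2
    if n < 2 or r1 == 0 or r2 == 0:
        return CochranArmitageResult(0.0, 1.0, True)
    tmean = float((t * c).sum() / n)
    var = (r1 * r2 / n**2) * float((t**2 * c).sum() - n * tmean**2)
    if var <= 0:
        return CochranArmitageResult(0.0, 1.0, True)
    big_t = float((t * (n1 - c * r1 / n)).sum())
    z = big_t / math.sqrt(var)
    p = 2.0 * float(norm.sf(abs(z)))
    return CochranArmitageResult(z, min(p, 1.0), False)


@dataclass
class TrendTestResult:
    """Per-chromosome trend-test outcome."""

    chrom: str
    z: float
    p_value: float
    p_adjusted: float
    significant: bool
    degenerate: bool = False
    n_ko: int = 0
    n_wt: int = 0


def flag_chromosomes(
    binned_wt: Sequence[BinnedVariantCounts],
    binned_ko: Sequence[BinnedVariantCounts],
    alpha: float = 0.05,
    scores: Literal["bin_index", "bin_midpoint_bp"] = "bin_index",
) -> list[TrendTestResult]:
    """Run the trend test on every chromosome shared by WT and KO.

    ``significant`` is driven by the raw per-chromosome p-value
    (``p < alpha``); the Bonferroni-adjusted p across tested chromosomes is
    reported alongside.  Chromosomes present on only one side are skipped
    with a logged warning.  Results are sorted by ascending p, ties by
    chromosome name.
    """
    from statsmodels.stats.multitest import multipletests

    wt_by = {b.chrom: b for b in binned_wt}
    ko_by = {b.chrom: b for b in binned_ko}
    for chrom in sorted(set(wt_by) ^ set(ko_by)):
        side = "WT" if chrom in wt_by else "KO"
        logger.warning("chromosome %s present only in %s counts; skipped", chrom, side)
    shared = sorted(set(wt_by) & set(ko_by))
    results: list[TrendTestResult] = []
    for chrom in shared:
        wt, ko = wt_by[chrom], ko_by[chrom]
        if wt.bin_size != ko.bin_size:
            raise ValueError(
                f"bin_size mismatch on {chrom}: WT {wt.bin_size} vs KO {ko.bin_size}"
            )
        k = max(wt.n_bins, ko.n_bins)
        row_wt = np.pad(np.asarray(wt.counts, float), (0, k - wt.n_bins))
        row_ko = np.pad(np.asarray(ko.counts, float), (0, k - ko.n_bins))
        if scores == "bin_index":
            sc = np.arange(k, dtype=float)
        elif scores == "bin_midpoint_bp":
            sc = (np.arange(k) + 0.5) * wt.bin_size
        else:
            raise ValueError(f"unknown scores {scores!r}")
        res = cochran_armitage(TrendTable(row_ko, row_wt, sc))
        results.append(
            TrendTestResult(
                chrom=chrom,
                z=res.z,
                p_value=res.p_value,
                p_adjusted=res.p_value,  # filled below
                significant=res.p_value < alpha,
                degenerate=res.degenerate,
                n_ko=int(row_ko.sum()),
                n_wt=int(row_wt.sum()),
            )
        )
    if results:
        adj = multipletests([r.p_value for r in results], method="bonferroni")[1]
        for r, pa in zip(results, adj):
            r.p_adjusted = float(pa)
    results.sort(key=lambda r: (r.p_value, r.chrom))
    return results


def estimate_footprint_interval(
    ko_linked: KoLinkedSet,
    chrom: str,
    ploidy_filter: Literal["homozygous_only", "all"] = "homozygous_only",
    *,
    segmentation: Literal["envelope", "gap_tolerant"] = "envelope",
    bin_size: int = DEFAULT_BIN_SIZE,
) -> tuple[int, int]:
    """Physical bounds (1-based inclusive) of the KO-linked footprint on
    ``chrom``.

    By default only homozygous (hom_alt) KO-linked variants define the
    interval, since the introgressed segment co-selected with the targeted
    allele is homozygous in the KO line.  ``envelope`` takes the min/max
    qualifying positions; ``gap_tolerant`` first drops leading/trailing
    empty bins and trims outlier variants separated from the main block by
    more than one empty bin, which guards the envelope against isolated
    stray calls.
    """
    positions = sorted(
        c.key.pos
        for c in ko_linked.variant_calls()
        if c.key.chrom == chrom
        and (ploidy_filter == "all" or classify_ploidy(c) is PloidyClass.HOMOZYGOUS)
    )
    if not positions:
        raise ValueError(
            f"no KO-linked variants on {chrom!r} passing ploidy filter {ploidy_filter!r}"
        )
    if segmentation == "envelope":
        return positions[0], positions[-1]
    if segmentation != "gap_tolerant":
        raise ValueError(f"unknown segmentation {segmentation!r}")
    # gap-tolerant: keep the largest run of occupied bins with <= 1 empty
    # internal bin between consecutive members
    bins = sorted({p // bin_size for p in positions})
    runs: list[list[int]] = [[bins[0]]]
    for b in bins[1:]:
        if b - runs[-1][-1] <= 2:  # allow one empty bin between occupied bins
            runs[-1].append(b)
        else:
            runs.append([b])
    def run_weight(run: list[int]) -> int:
        lo, hi = run[0], run[-1]
        return sum(1 for p in positions if lo * bin_size <= p < (hi + 1) * bin_size)
    best = max(runs, key=run_weight)
    inside = [p for p in positions if best[0] * bin_size <= p < (best[-1] + 1) * bin_size]
    return inside[0], inside[-1]


def estimate_backcross_generations(extent_cM: float) -> int:
    """Estimate backcross generations N from the footprint's genetic extent.

    Uses the classical congenic expectation cM = 200/N: after N backcross
    generations the donor segment retained around the selected locus spans
    about 200/N cM (100/N expected on each flank).  N is rounded to the
    nearest integer (half away from zero), minimum 1.
    """
    if extent_cM <= 0:
        raise ValueError(f"extent_cM must be > 0, got {extent_cM}")
    return max(1, int(math.floor(200.0 / extent_cM + 0.5)))


@dataclass
class FootprintInterval:
    """A KO-linked introgressed interval with genetic extent and estimated N."""

    chrom: str
    start_bp: int
    end_bp: int
    extent_cM: float
    estimated_N: int

    def __post_init__(self) -> None:
        if self.start_bp > self.end_bp:
            raise ValueError("start_bp must be <= end_bp")
        if self.extent_cM < 0:
            raise ValueError("extent_cM must be >= 0")
        if self.estimated_N < 1:
            raise ValueError("estimated_N must be >= 1")

    def to_bed_line(self) -> str:
        """BED interval (0-based half-open) with extent and N in extra columns."""
        return (
            f"{self.chrom}\t{self.start_bp - 1}\t{self.end_bp}\t"
            f"footprint_cM={self.extent_cM:.2f};N={self.estimated_N}"
        )


def build_footprint_interval(
    ko_linked: KoLinkedSet,
    chrom: str,
    genetic_map: GeneticMap,
    ploidy_filter: Literal["homozygous_only", "all"] = "homozygous_only",
    segmentation: Literal["envelope", "gap_tolerant"] = "envelope",
) -> FootprintInterval:
    """Estimate the footprint interval on ``chrom``, convert its physical
    bounds to cM, and estimate the number of backcross generations."""
    start, end = estimate_footprint_interval(
        ko_linked, chrom, ploidy_filter, segmentation=segmentation
    )
    extent = genetic_map.interval_cm(chrom, start, end)
    n_est = estimate_backcross_generations(extent) if extent > 0 else 1
    return FootprintInterval(chrom, start, end, extent, n_est)
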