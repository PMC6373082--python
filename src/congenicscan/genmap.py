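"""Physical-to-genetic map conversion.

A :class:`GeneticMap` holds per-chromosome anchor lists of (bp, cM) pairs,
strictly increasing in both coordinates, read from a TSV with columns
``chrom  bp  cM``.  Positions between anchors are linearly interpolated;
positions outside the anchor range are linearly extrapolated with the slope
of the terminal segment, so the map is monotone non-decreasing everywhere.
A constant-rate map (default 0.5 cM/Mb, a genome-wide average recombination
rate for the mouse) is available as a fallback when no map file is given.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

__all__ = ["GeneticMap", "DEFAULT_CM_PER_MB"]

DEFAULT_CM_PER_MB = 0.5


@dataclass
class GeneticMap:
    """Per-chromosome genetic-map anchors with interpolation.

    ``anchors`` maps chromosome name to two parallel float arrays
    ``(bp, cM)``, each strictly increasing with at least two entries.
    ``fallback_rate_cm_per_mb`` (optional) is used for chromosomes absent
    from the map; when it is None such chromosomes raise ``KeyError``.
    """

    anchors: dict[str, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)
    fallback_rate_cm_per_mb: float | None = None

    @classmethod
    def from_tsv(
        cls, path: str | os.PathLike, fallback_rate_cm_per_mb: float | None = None
    ) -> "GeneticMap":
        """Read anchors from a TSV with header ``chrom  bp  cM``."""
        import pandas as pd

        df = pd.read_csv(path, sep="\t")
        expected = {"chrom", "bp", "cM"}
        if not expected.issubset(df.columns):
            raise ValueError(
                f"genetic map must have columns {sorted(expected)}, got {list(df.columns)}"
            )
        gm = cls(fallback_rate_cm_per_mb=fallback_rate_cm_per_mb)
        for chrom, grp in df.groupby("chrom", sort=False):
            grp = grp.sort_values("bp")
            gm.add_chromosome(str(chrom), grp["bp"].to_numpy(float), grp["cM"].to_numpy(float))
        return gm

    @classmethod
    def constant_rate(
        cls,
        chromosome_lengths: Mapping[str, int],
        rate_cm_per_mb: float = DEFAULT_CM_PER_MB,
    ) -> "GeneticMap":
        """Build a two-anchor constant-rate map for each chromosome."""
        gm = cls(fallback_rate_cm_per_mb=rate_cm_per_mb)
        for chrom, length in chromosome_lengths.items():
            gm.add_chromosome(
                chrom,
                np.array([0.0, float(length)]),
                np.array([0.0, rate_cm_per_mb * length / 1e6]),
            )
        return gm

    def add_chromosome(self, chrom: str, bp: np.ndarray, cm: np.ndarray) -> None:
        bp = np.asarray(bp, float)
        cm = np.asarray(cm, float)
        if bp.size < 2:
            raise ValueError(f"chromosome {chrom!r}: need >= 2 anchors, got {bp.size}")
        if not (np.all(np.diff(bp) > 0) and np.all(np.diff(cm) > 0)):
            raise ValueError(
                f"chromosome {chrom!r}: anchors must be strictly increasing in bp and cM"
            )
        self.anchors[chrom] = (bp, cm)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.anchors

    def interpolate(self, chrom: str, bp: float) -> float:
        """cM position of ``bp`` on ``chrom`` (linear interpolation; linear
        extrapolation beyond the terminal anchors)."""
        if chrom not in self.anchors:
            if self.fallback_rate_cm_per_mb is None:
                raise KeyError(
                    f"chromosome {chrom!r} absent from genetic map and no fallback rate set"
                )
            return float(bp) * self.fallback_rate_cm_per_mb / 1e6
        xs, ys = self.anchors[chrom]
        if bp < xs[0]:
            slope = (ys[1] - ys[0]) / (xs[1] - xs[0])
            return float(ys[0] + (bp - xs[0]) * slope)
        if bp > xs[-1]:
            slope = (ys[-1] - ys[-2]) / (xs[-1] - xs[-2])
            return float(ys[-1] + (bp - xs[-1]) * slope)
        return float(np.interp(bp, xs, ys))

    def interval_cm(self, chrom: str, start_bp: float, end_bp: float) -> float:
        """Genetic length in cM of the physical interval [start_bp, end_bp]."""
        if end_bp < start_bp:
            raise ValueError("end_bp must be >= start_bp")
        return self.interpolate(chrom, end_bp) - self.interpolate(chrom, start_bp)

    def inverse(self, chrom: str, cm: float) -> float:
        """bp position at genetic position ``cm`` (inverse interpolation)."""
        if chrom not in self.anchors:
            if self.fallback_rate_cm_per_mb is None:
                raise KeyError(f"chromosome {chrom!r} absent from genetic map")
            return cm * 1e6 / self.fallback_rate_cm_per_mb
        xs, ys = self.anchors[chrom]
        if cm < ys[0]:
            slope = (xs[1] - xs[0]) / (ys[1] - ys[0])
            return float(xs[0] + (cm - ys[0]) * slope)
        if cm > ys[-1]:
            slope = (xs[-1] - xs[-2]) / (ys[-1] - ys[-2])
            return float(xs[-1] + (cm - ys[-1]) * slope)
        return float(np.interp(cm, ys, xs))

    def chrom_length_cm(self, chrom: str) -> float:
        xs, ys = self.anchors[chrom]
        return float(ys[-1] - ys[0])

    def to_tsv(self, path: str | os.PathLike) -> None:
        with open(os.fspath(path), "w") as fh:
            fh.write("chrom\tbp\tcM\n")
            for chrom, (xs, ys) in self.anchors.items():
                for x, y in zip(xs, ys):
                    fh.write(f"{chrom}\t{int(x)}\t{y:.6f}\n")
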