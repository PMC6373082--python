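"""Expression-on-genotype regression screen for candidate modifier genes.

Congenic genes inside the footprint carry donor-strain alleles whose
expression can track the number of donor copies rather than the targeted
gene itself.  Coding the genotypes on an additive dosage scale
(WT = 1, Het = 0.5, KO = 0 donor copies of the recipient allele) and
regressing normalized expression on the code identifies genes whose
expression depends linearly on genotype — candidate cis-eQTLs / modifier
genes.  The module consumes a pre-normalized count table; normalization is
deliberately out of scope.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GENOTYPE_CODES",
    "CountTable",
    "EqtlScreenResult",
    "encode_genotypes",
    "screen_eqtl",
    "select_candidates",
]

GENOTYPE_CODES = {"WT": 1.0, "HET": 0.5, "KO": 0.0}


def encode_genotypes(labels: Sequence[str]) -> list[float]:
    """Additive dosage codes: WT -> 1.0, HET -> 0.5, KO -> 0.0."""
    if len(labels) == 0:
        raise ValueError("labels must be non-empty")
    try:
        return [GENOTYPE_CODES[lab] for lab in labels]
    except KeyError as exc:
        raise ValueError(
            f"unknown genotype label {exc.args[0]!r}; expected one of {sorted(GENOTYPE_CODES)}"
        ) from None


@dataclass
class CountTable:
    """Normalized expression (genes x samples) with per-sample genotype and
    condition labels.

    ``values`` is a DataFrame indexed by gene id with sample ids as columns;
    ``genotypes`` and ``conditions`` map sample id -> label.  Values are
    expected normalized and non-negative.
    """

    values: pd.DataFrame
    genotypes: dict[str, str]
    conditions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            raise ValueError("duplicate gene identifiers")
        if self.values.columns.duplicated().any():
            raise ValueError("duplicate sample identifiers")
        missing = [s for s in self.values.columns if s not in self.genotypes]
        if missing:
            raise ValueError(f"samples without genotype label: {missing}")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def for_condition(self, condition: str) -> "CountTable":
        cols = [s for s in self.samples if self.conditions.get(s) == condition]
        if not cols:
            raise ValueError(f"no samples with condition {condition!r}")
        return CountTable(self.values[cols], self.genotypes, self.conditions)

    @classmethod
    def from_tsv(
        cls, counts_path: str | os.PathLike, samples_path: str | os.PathLike
    ) -> "CountTable":
        """Read a counts TSV (first column gene id, header of sample ids)
        plus a sample-sheet TSV (sample_id, genotype[, condition])."""
        values = pd.read_csv(counts_path, sep="\t", index_col=0)
        sheet = pd.read_csv(samples_path, sep="\t", dtype=str)
        if "sample_id" not in sheet.columns or "genotype" not in sheet.columns:
            raise ValueError("sample sheet needs 'sample_id' and 'genotype' columns")
        genotypes = dict(zip(sheet["sample_id"], sheet["genotype"]))
        conditions = (
            dict(zip(sheet["sample_id"], sheet["condition"]))
            if "condition" in sheet.columns
            else {}
        )
        return cls(values, genotypes, conditions)

    def to_tsv(
        self, counts_path: str | os.PathLike, samples_path: str | os.PathLike
    ) -> None:
        self.values.to_csv(counts_path, sep="\t")
        with open(os.fspath(samples_path), "w") as fh:
            fh.write("sample_id\tgenotype\tcondition\n")
            for s in self.samples:
                fh.write(f"{s}\t{self.genotypes[s]}\t{self.conditions.get(s, '.')}\n")


@dataclass
class EqtlScreenResult:
    """Per-gene slope and significance of expression-on-genotype OLS."""

    gene: str
    slope: float
    intercept: float
    p_value: float
    stderr: float
    selected: bool
    perfect_fit: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p_value must be in [0, 1]")


def screen_eqtl(
    table: CountTable,
    alpha: float = 0.05,
    *,
    fdr: bool = False,
) -> list[EqtlScreenResult]:
    """Per-gene ordinary least squares of expression on genotype code.

    The p-value is the two-sided t-test of slope != 0 with n - 2 degrees of
    freedom; ``selected`` means p < alpha (raw by default; with ``fdr=True``
    selection uses Benjamini-Hochberg adjusted p-values instead).  A gene
    fitting perfectly (zero residual variance, nonzero slope) is reported
    with the smallest positive p and flagged ``perfect_fit``.  With only two
    genotype groups the regression degenerates to a two-group comparison;
    this is allowed but requires >= 2 distinct codes and >= 3 samples.
    """
    codes = np.asarray(encode_genotypes([table.genotypes[s] for s in table.samples]))
    if len(codes) < 3:
        raise ValueError(f"need >= 3 samples, got {len(codes)}")
    if len(np.unique(codes)) < 2:
        raise ValueError("all samples share one genotype; slope is unidentifiable")

    results: list[EqtlScreenResult] = []
    for gene, row in table.values.iterrows():
        y = row.to_numpy(float)
        fit = stats.linregress(codes, y)
        p, perfect = float(fit.pvalue), False
        resid = y - (fit.intercept + fit.slope * codes)
        if np.allclose(resid, 0.0, atol=1e-12 * max(1.0, float(np.abs(y).max()))):
            if fit.slope != 0.0:
                p, perfect = float(np.nextafter(0.0, 1.0)), True
            else:
                p = 1.0  # constant gene: no trend
        results.append(
            EqtlScreenResult(
                gene=str(gene),
                slope=float(fit.slope),
                intercept=float(fit.intercept),
                p_value=p,
                stderr=float(fit.stderr),
                selected=False,
                perfect_fit=perfect,
            )
        )
    if fdr:
        from statsmodels.stats.multitest import multipletests

        rej, _, _, _ = multipletests([r.p_value for r in results], alpha=alpha, method="fdr_bh")
        for r, rj in zip(results, rej):
            r.selected = bool(rj)
    else:
        for r in results:
            r.selected = r.p_value < alpha
    return results


def select_candidates(
    control: Sequence[EqtlScreenResult],
    perturbed: Sequence[EqtlScreenResult],
) -> list[str]:
    """Genes selected in BOTH conditions, ordered by ascending control p.

    Requiring significance under both a control and a perturbed condition
    guards the screen against condition-specific expression artifacts.
    """
    sel_perturbed = {r.gene for r in perturbed if r.selected}
    both = [r for r in control if r.selected and r.gene in sel_perturbed]
    both.sort(key=lambda r: (r.p_value, r.gene))
    return [r.gene for r in both]
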