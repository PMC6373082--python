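"""Zygosity of footprint variants and Mendelian cross-validation.

In an inbred congenic line the introgressed segment co-selected with the
targeted allele is expected homozygous in the KO; a heterozygous littermate
should then carry the same variants heterozygously.  This module classifies
call zygosity ("ploidy" in the loose sense used for congenic footprints:
hom_alt vs het), profiles it in genomic bins per sample, and annotates the
KO-linked variants against a heterozygous littermate's calls as a Mendelian
consistency check of the footprint.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

from .variants import Genotype, GenotypeCallSet, SiteKey, VariantCall

__all__ = [
    "PloidyClass",
    "PloidyProfile",
    "MendelianAnnotation",
    "classify_ploidy",
    "ploidy_profile",
    "mendelian_annotate",
]


class PloidyClass(enum.Enum):
    HOMOZYGOUS = "homozygous"
    HETEROZYGOUS = "heterozygous"
    OTHER = "other"


def classify_ploidy(call: VariantCall) -> PloidyClass:
    """hom_alt -> homozygous, het -> heterozygous, hom_ref/missing -> other.

    Only hom_alt counts as homozygous: footprint variants are donor alleles,
    so a homozygous-reference call is never footprint evidence.
    """
    if call.genotype is Genotype.HOM_ALT:
        return PloidyClass.HOMOZYGOUS
    if call.genotype is Genotype.HET:
        return PloidyClass.HETEROZYGOUS
    return PloidyClass.OTHER


@dataclass
class PloidyProfile:
    """Per-bin homozygous/heterozygous call counts on one chromosome."""

    sample_id: str
    chrom: str
    bin_size: int
    hom_counts: list[int]
    het_counts: list[int]

    @property
    def n_bins(self) -> int:
        return len(self.hom_counts)


def ploidy_profile(
    callset: GenotypeCallSet, bin_size: int = 10_000_000
) -> list[PloidyProfile]:
    """Bin hom_alt and het calls per chromosome (half-open windows
    ``[k*bin_size, (k+1)*bin_size)`` on the 1-based coordinate).

    Run per sample (before any consensus) this exposes replicate-to-
    replicate zygosity variability across a segregating footprint.
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be > 0")
    from .variants import _chrom_sort_key

    per_chrom: dict[str, tuple[list[int], list[int]]] = {}
    for call in callset.calls.values():
        cls = classify_ploidy(call)
        if cls is PloidyClass.OTHER:
            continue
        hom, het = per_chrom.setdefault(call.key.chrom, ([], []))
        (hom if cls is PloidyClass.HOMOZYGOUS else het).append(call.key.pos)
    out = []
    for chrom in sorted(per_chrom, key=_chrom_sort_key):
        hom, het = per_chrom[chrom]
        n_bins = max(hom + het) // bin_size + 1
        hom_c = np.bincount([p // bin_size for p in hom], minlength=n_bins)
        het_c = np.bincount([p // bin_size for p in het], minlength=n_bins)
        out.append(
            PloidyProfile(callset.label, chrom, bin_size, hom_c.tolist(), het_c.tolist())
        )
    return out


@dataclass
class MendelianAnnotation:
    """KO-linked keys confirmed heterozygous in a het littermate."""

    annotated: set[SiteKey] = field(default_factory=set)
    n_ko_linked: int = 0

    @property
    def variant_coverage(self) -> float:
        return len(self.annotated) / self.n_ko_linked if self.n_ko_linked else 0.0


def mendelian_annotate(
    ko_linked: GenotypeCallSet,
    het_sample: GenotypeCallSet,
    wt_sample: GenotypeCallSet,
) -> MendelianAnnotation:
    """Annotate KO-linked variants with a heterozygous littermate's calls.

    The littermate's calls are first reduced to those absent from the WT
    sample (shared background removed), then to heterozygous calls; a
    KO-linked key is ``annotated`` when present in that reduced set.  Under
    Mendelian inheritance of a homozygous footprint the coverage approaches
    1 inside the footprint, so a low coverage flags either a segregating
    (non-fixed) footprint or spurious KO-linked calls.
    """
    if not ko_linked.calls:
        raise ValueError("ko_linked is empty")
    wt_keys = wt_sample.keys()
    het_keys = {
        c.key
        for c in het_sample.calls.values()
        if c.key not in wt_keys and c.genotype is Genotype.HET
    }
    annotated = {k for k in ko_linked.calls if k in het_keys}
    return MendelianAnnotation(annotated=annotated, n_ko_linked=len(ko_linked.calls))
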