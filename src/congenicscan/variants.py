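"""Genotype-call containers, VCF input/output, and hard filtering.

The unit of identity throughout the package is the :class:`SiteKey`
``(chrom, pos, ref, alt)`` with a single ALT allele per key; multiallelic
VCF records are split into one call per ALT on read.  Coordinates are
1-based inclusive (VCF convention).  Indels are matched by their exact
``(pos, ref, alt)`` strings — inputs are expected to be pre-normalized
(left-aligned) by the caller that produced them; no re-normalization is
attempted here.
"""

from __future__ import annotations

import enum
import gzip
import os
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, NamedTuple

__all__ = [
    "Genotype",
    "SiteKey",
    "VariantCall",
    "GenotypeCallSet",
    "VcfParseError",
    "read_vcf",
    "write_vcf",
    "write_tsv",
    "apply_hard_filters",
    "rename_chromosomes",
]


class Genotype(enum.Enum):
    """Diploid genotype state of a call at one site/ALT allele."""

    HOM_REF = "hom_ref"
    HET = "het"
    HOM_ALT = "hom_alt"
    MISSING = "missing"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class SiteKey(NamedTuple):
    """Identity of a variant: chromosome, 1-based position, REF, single ALT."""

    chrom: str
    pos: int
    ref: str
    alt: str

    def validate(self) -> "SiteKey":
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if not self.ref or not self.alt:
            raise ValueError("ref and alt must be non-empty")
        if "," in self.alt:
            raise ValueError("alt must hold exactly one allele")
        return self


@dataclass(frozen=True)
class VariantCall:
    """One diploid genotype call with its quality and depth.

    ``qual`` is the Phred-scaled site quality; ``depth`` the read depth (DP).
    Either may be ``None`` when absent from the source VCF, in which case the
    call conservatively fails the corresponding hard filter.
    """

    key: SiteKey
    genotype: Genotype
    qual: float | None
    depth: int | None
    sample_id: str = ""

    def __post_init__(self) -> None:
        self.key.validate()
        if self.qual is not None and self.qual < 0:
            raise ValueError(f"qual must be >= 0, got {self.qual}")
        if self.depth is not None and self.depth < 0:
            raise ValueError(f"depth must be >= 0, got {self.depth}")


@dataclass
class GenotypeCallSet:
    """Keyed collection of calls for one sample (or one consensus genotype).

    ``label`` is a genotype label (``WT``/``HET``/``KO``) or a sample name.
    At most one call per :class:`SiteKey`.
    """

    label: str
    calls: dict[SiteKey, VariantCall] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.calls)

    def __contains__(self, key: SiteKey) -> bool:
        return key in self.calls

    def __iter__(self) -> Iterator[VariantCall]:
        return iter(self.calls.values())

    def add(self, call: VariantCall) -> None:
        if call.key in self.calls:
            raise ValueError(f"duplicate call at {call.key}")
        self.calls[call.key] = call

    def keys(self) -> set[SiteKey]:
        return set(self.calls)

    def variant_calls(self, *, include_missing: bool = False) -> list[VariantCall]:
        """Calls carrying an alternate allele (het or hom_alt).

        hom_ref calls are retained on read but are never counted as variants;
        missing (``./.``) genotypes are excluded from downstream set
        operations unless explicitly requested.
        """
        keep = {Genotype.HET, Genotype.HOM_ALT}
        if include_missing:
            keep = keep | {Genotype.MISSING}
        return [c for c in self.calls.values() if c.genotype in keep]

    def subset(self, keys: Iterable[SiteKey]) -> "GenotypeCallSet":
        wanted = set(keys)
        return GenotypeCallSet(
            self.label, {k: c for k, c in self.calls.items() if k in wanted}
        )


class VcfParseError(ValueError):
    """Raised when a VCF file cannot be parsed or lacks a requested sample."""


def _genotype_from_alleles(alleles: list[int], alt_index: int) -> Genotype:
    """Genotype state for one ALT allele from a diploid allele-index pair."""
    if any(a < 0 for a in alleles):
        return Genotype.MISSING
    n = sum(1 for a in alleles if a == alt_index)
    if n == 2:
        return Genotype.HOM_ALT
    if n == 1:
        return Genotype.HET
    return Genotype.HOM_REF


def read_vcf(
    path: str | os.PathLike,
    sample_id: str | None = None,
    *,
    chrom_map: Mapping[str, str] | None = None,
) -> GenotypeCallSet:
    """Read one sample's calls from a VCF (v4.x, optionally gzipped).

    Parameters
    ----------
    path
        VCF file; plain or gzip/bgzip compressed.
    sample_id
        Sample column to read.  May be omitted for a single-sample file, in
        which case that sample is used.  A missing sample raises
        :class:`VcfParseError` listing the samples present.
    chrom_map
        Optional explicit chromosome-name mapping applied verbatim (e.g.
        ``{"14": "chr14"}``) to reconcile naming dialects between files.
        Names not in the mapping are preserved as written.

    Returns
    -------
    GenotypeCallSet
        One :class:`VariantCall` per (split) ALT allele.  hom_ref and missing
        genotypes are retained (flagged by their :class:`Genotype`) but
        excluded from variant counting downstream.  Multiallelic records are
        split into one call per ALT sharing pos/ref.
    """
    from cyvcf2 import VCF

    path = os.fspath(path)
    try:
        vcf = VCF(path)
    except Exception as exc:  # htslib reports its own diagnostics
        raise VcfParseError(f"cannot parse VCF {path!r}: {exc}") from exc

    samples = list(vcf.samples)
    if sample_id is None:
        if len(samples) == 1:
            sample_id = samples[0]
        elif len(samples) == 0:
            sample_id = os.path.basename(path)
        else:
            raise VcfParseError(
                f"{path!r} is multi-sample; pass sample_id (available: {samples})"
            )
    elif samples and sample_id not in samples:
        raise VcfParseError(
            f"sample {sample_id!r} not in {path!r}; available samples: {samples}"
        )
    sidx = samples.index(sample_id) if sample_id in samples else None

    out = GenotypeCallSet(sample_id)
    try:
        for rec in vcf:
            chrom = rec.CHROM
            if chrom_map and chrom in chrom_map:
                chrom = chrom_map[chrom]
            qual = rec.QUAL  # None when '.'
            if sidx is not None:
                alleles = list(rec.genotypes[sidx][:-1])
                dp_arr = rec.format("DP")
                if dp_arr is not None and int(dp_arr[sidx][0]) >= 0:
                    depth = int(dp_arr[sidx][0])
                else:
                    depth = rec.INFO.get("DP")
            else:  # site-only VCF: no FORMAT columns at all
                alleles = [1, 1]
                depth = rec.INFO.get("DP")
            depth = int(depth) if depth is not None else None
            for j, alt in enumerate(rec.ALT, start=1):
                key = SiteKey(chrom, rec.POS, rec.REF, alt)
                call = VariantCall(
                    key=key,
                    genotype=_genotype_from_alleles(alleles, j),
                    qual=float(qual) if qual is not None else None,
                    depth=depth,
                    sample_id=sample_id,
                )
                if key not in out.calls:  # keep first on pathological dups
                    out.calls[key] = call
    except VcfParseError:
        raise
    except Exception as exc:
        raise VcfParseError(f"malformed VCF {path!r}: {exc}") from exc
    return out


_VCF_HEADER = """\
##fileformat=VCFv4.2
##source=congenicscan
##INFO=<ID=DP,Number=1,Type=Integer,Description="Read depth">
{extra_info}##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
{contigs}#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}
"""

_GT_STRING = {
    Genotype.HOM_REF: "0/0",
    Genotype.HET: "0/1",
    Genotype.HOM_ALT: "1/1",
    Genotype.MISSING: "./.",
}


def _chrom_sort_key(chrom: str) -> tuple:
    base = chrom[3:] if chrom.startswith("chr") else chrom
    return (0, int(base)) if base.isdigit() else (1, base)


def write_vcf(
    calls: Iterable[VariantCall],
    path: str | os.PathLike,
    sample: str = "SAMPLE",
    *,
    contig_lengths: Mapping[str, int] | None = None,
    info_tags: Mapping[SiteKey, Mapping[str, str]] | None = None,
    extra_info_headers: Iterable[tuple[str, str, str]] = (),
) -> None:
    """Write calls as a single-sample VCF v4.2 (plain text, or .gz by suffix).

    ``info_tags`` attaches per-site INFO ``KEY=value`` pairs (e.g. the
    ``KO_LINKED_REASON`` / ``ORIGIN`` annotations); each tag used must be
    declared through ``extra_info_headers`` as ``(id, type, description)``.
    Records are written coordinate-sorted.
    """
    path = os.fspath(path)
    extra = "".join(
        f'##INFO=<ID={i},Number=1,Type={t},Description="{d}">\n'
        for i, t, d in extra_info_headers
    )
    contigs = ""
    if contig_lengths:
        contigs = "".join(
            f"##contig=<ID={c},length={l}>\n"
            for c, l in sorted(contig_lengths.items(), key=lambda x: _chrom_sort_key(x[0]))
        )
    lines = [_VCF_HEADER.format(extra_info=extra, contigs=contigs, sample=sample)]
    ordered = sorted(calls, key=lambda c: (_chrom_sort_key(c.key.chrom), c.key.pos, c.key.alt))
    for c in ordered:
        info = []
        if c.depth is not None:
            info.append(f"DP={c.depth}")
        if info_tags and c.key in info_tags:
            info.extend(f"{k}={v}" for k, v in info_tags[c.key].items())
        qual = "." if c.qual is None else f"{c.qual:g}"
        dp = "." if c.depth is None else str(c.depth)
        lines.append(
            f"{c.key.chrom}\t{c.key.pos}\t.\t{c.key.ref}\t{c.key.alt}\t{qual}\t.\t"
            f"{';'.join(info) or '.'}\tGT:DP\t{_GT_STRING[c.genotype]}:{dp}\n"
        )
    opener = gzip.open if path.endswith(".gz") else open
    with opener(path, "wt") as fh:
        fh.writelines(lines)


def write_tsv(
    calls: Iterable[VariantCall],
    path: str | os.PathLike,
    *,
    annotations: Mapping[SiteKey, str] | None = None,
    annotation_column: str = "annotation",
) -> None:
    """Write calls as a TSV (chrom, pos, ref, alt, genotype, qual, depth[, annotation])."""
    cols = ["chrom", "pos", "ref", "alt", "genotype", "qual", "depth"]
    if annotations is not None:
        cols.append(annotation_column)
    with open(os.fspath(path), "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for c in sorted(calls, key=lambda c: (_chrom_sort_key(c.key.chrom), c.key.pos)):
            row = [
                c.key.chrom,
                str(c.key.pos),
                c.key.ref,
                c.key.alt,
                c.genotype.value,
                "." if c.qual is None else f"{c.qual:g}",
                "." if c.depth is None else str(c.depth),
            ]
            if annotations is not None:
                row.append(annotations.get(c.key, "."))
            fh.write("\t".join(row) + "\n")


def apply_hard_filters(
    callset: GenotypeCallSet,
    min_depth_exclusive: int = 10,
    min_qual_exclusive: float = 30.0,
) -> GenotypeCallSet:
    """Keep only calls with DP strictly above ``min_depth_exclusive`` and
    QUAL strictly above ``min_qual_exclusive``.

    The defaults are the standard hard thresholds for diploid calling from
    short-read data (DP > 10, QUAL > 30).  Calls lacking DP or QUAL fail the
    corresponding filter (conservative).  The input set is not modified.
    """
    if min_depth_exclusive < 0 or min_qual_exclusive < 0:
        raise ValueError("filter thresholds must be >= 0")
    kept = {
        k: c
        for k, c in callset.calls.items()
        if c.depth is not None
        and c.depth > min_depth_exclusive
        and c.qual is not None
        and c.qual > min_qual_exclusive
    }
    return GenotypeCallSet(callset.label, kept)


def rename_chromosomes(
    callset: GenotypeCallSet, chrom_map: Mapping[str, str]
) -> GenotypeCallSet:
    """Return a copy with chromosome names mapped through ``chrom_map``.

    Only an explicit mapping is applied (e.g. ``{"14": "chr14"}``); there is
    no silent auto-renaming between naming dialects.
    """
    out = GenotypeCallSet(callset.label)
    for key, c in callset.calls.items():
        if key.chrom in chrom_map:
            key = SiteKey(chrom_map[key.chrom], key.pos, key.ref, key.alt)
            c = VariantCall(key, c.genotype, c.qual, c.depth, c.sample_id)
        out.calls[key] = c
    return out
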