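"""Backcross-breeding simulator with known ground truth.

The generator makes the congenic breeding scheme executable: an F1 carrier
heterozygous for a donor-strain genome is backcrossed N times to the
recipient strain, selecting at each generation an offspring that carries
the targeted allele.  Meioses on the target chromosome are modeled as
crossovers arising as a Poisson process on the genetic-map scale (one
crossover per 100 cM per meiosis; no interference — the Haldane model),
which is the process behind the classical expectation that the donor
segment retained around the selected locus spans about 200/N cM after N
backcross generations.  A final intercross founds the line: the carrier's
donor haplotype on the target chromosome is fixed to homozygosity in KO
samples, carried heterozygously by the het littermate, and absent from WT
littermates.  Donor segments on non-target chromosomes survive each
backcross with probability 1/2 (whole-chromosome granularity) and then
segregate Mendelianly among littermates, reproducing the mixed-background
residue seen at low backcross numbers.

Variant layers emitted per sample:

* donor variants — a Poisson process along each chromosome at the
  configured density; genotype follows the sample's donor-copy mosaic;
* shared background variants — homozygous in every sample, emulating
  colony variants not removed by reference subtraction;
* drift variants — novel homozygous variants private to one genotype
  group, emulating variants fixed by genetic drift.

The same seed yields byte-identical VCFs and truth records.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np

from .genmap import GeneticMap
from .variants import Genotype, GenotypeCallSet, SiteKey, VariantCall, write_vcf

__all__ = [
    "SimulationConfig",
    "TruthRecord",
    "CohortSimulation",
    "simulate_congenic_cohort",
    "simulate_count_table",
    "default_eqtl_slopes",
    "donor_reference_callset",
]

_BASES = "ACGT"

DEFAULT_CHROMOSOMES: dict[str, int] = {
    "chr1": 180_000_000,
    "chr2": 160_000_000,
    "chr5": 150_000_000,
    "chr11": 120_000_000,
    "chr14": 125_000_000,
}


@dataclass
class SimulationConfig:
    """Study conditions for one simulated congenic cohort.

    Defaults emulate a mouse knockout line targeted near the distal end of a
    mid-sized chromosome (the clearest real-world footprint configuration),
    sampled as one WT embryo, one heterozygous littermate and three KO
    littermates, with RNA-seq-like call depth and quality.
    """

    chromosome_lengths: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_CHROMOSOMES)
    )
    rate_cm_per_mb: float = 0.5
    genetic_map: GeneticMap | None = None  # constant-rate map built if None
    donor_density_per_mb: float = 1.0
    background_density_per_mb: float = 0.1
    drift_density_per_mb: float = 0.01
    target_chrom: str = "chr5"
    target_bp: int = 134_000_000
    n_backcrosses: int = 10
    n_wt: int = 1
    n_het: int = 1
    n_ko: int = 3
    intercross: bool = True
    dropout_rate: float = 0.02
    depth_mean: float = 40.0
    qual_shape: float = 3.0
    qual_scale: float = 100.0
    seed: int = 0

    def validate(self) -> None:
        if self.target_chrom not in self.chromosome_lengths:
            raise ValueError(f"target chromosome {self.target_chrom!r} not in genome")
        if not (1 <= self.target_bp <= self.chromosome_lengths[self.target_chrom]):
            raise ValueError("target_bp outside its chromosome")
        if self.donor_density_per_mb <= 0:
            raise ValueError("donor_density_per_mb must be > 0")
        if self.background_density_per_mb < 0 or self.drift_density_per_mb < 0:
            raise ValueError("densities must be >= 0")
        if self.n_backcrosses < 1:
            raise ValueError("n_backcrosses must be >= 1")
        if not (0.0 <= self.dropout_rate < 1.0):
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.n_ko < 1 or self.n_wt < 0 or self.n_het < 0:
            raise ValueError("need >= 1 KO sample; n_wt/n_het >= 0")

    def map(self) -> GeneticMap:
        if self.genetic_map is not None:
            return self.genetic_map
        return GeneticMap.constant_rate(self.chromosome_lengths, self.rate_cm_per_mb)


Interval = tuple[int, int]  # 1-based inclusive donor interval


def _intersect(intervals: Sequence[Interval], lo: int, hi: int) -> list[Interval]:
    """Clip a sorted interval list to [lo, hi] (1-based inclusive)."""
    out = []
    for s, e in intervals:
        s2, e2 = max(s, lo), min(e, hi)
        if s2 <= e2:
            out.append((s2, e2))
    return out


def _covers(intervals: Sequence[Interval], pos: int) -> bool:
    return any(s <= pos <= e for s, e in intervals)


def _gamete(
    rng: np.random.Generator,
    hap_donor: Sequence[Interval],
    chrom: str,
    chrom_len: int,
    gmap: GeneticMap,
) -> list[Interval]:
    """One meiotic product of a (donor-mosaic, pure-recipient) pair.

    Crossovers are Poisson on the cM scale; the gamete alternates between
    the two parental haplotypes at each breakpoint starting from a random
    phase, so its donor content is the mosaic haplotype's content restricted
    to the segments where the mosaic strand is active.
    """
    cm_start = gmap.interpolate(chrom, 1)
    cm_end = gmap.interpolate(chrom, chrom_len)
    length_cm = cm_end - cm_start
    n_x = rng.poisson(length_cm / 100.0)
    breaks_cm = np.sort(rng.uniform(cm_start, cm_end, size=n_x))
    breaks_bp = [int(round(gmap.inverse(chrom, c))) for c in breaks_cm]
    phase = int(rng.integers(2))  # 0: start on the mosaic strand
    out: list[Interval] = []
    edges = [1, *[b for b in breaks_bp if 1 < b <= chrom_len], chrom_len + 1]
    active = phase == 0
    for lo, hi in zip(edges[:-1], edges[1:]):
        if active:
            out.extend(_intersect(hap_donor, lo, hi - 1))
        active = not active
    return out


@dataclass
class TruthRecord:
    """Ground truth of a simulated cohort.

    ``variants`` lists every simulated site as
    ``(chrom, pos, ref, alt, origin)`` with origin in
    {donor, background, drift_<GROUP>}; ``sample_mosaics`` gives per-sample
    donor-copy intervals ``(start_bp, end_bp, copies)`` per chromosome.
    """

    n_backcrosses: int
    target_chrom: str
    target_bp: int
    footprint_start_bp: int
    footprint_end_bp: int
    footprint_extent_cm: float
    fixed_haplotype: list[Interval]
    residual_chromosomes: list[str]
    sample_mosaics: dict[str, dict[str, list[tuple[int, int, int]]]]
    variants: list[tuple[str, int, str, str, str]]
    sample_groups: dict[str, str]

    def donor_variant_keys(self) -> set[SiteKey]:
        return {
            SiteKey(c, p, r, a) for c, p, r, a, o in self.variants if o == "donor"
        }

    def footprint_variant_keys(self) -> set[SiteKey]:
        return {
            SiteKey(c, p, r, a)
            for c, p, r, a, o in self.variants
            if o == "donor"
            and c == self.target_chrom
            and self.footprint_start_bp <= p <= self.footprint_end_bp
        }

    def to_json(self, path: str | os.PathLike) -> None:
        with open(os.fspath(path), "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, default=list)


@dataclass
class CohortSimulation:
    """In-memory result of :func:`simulate_congenic_cohort`."""

    config: SimulationConfig
    truth: TruthRecord
    samples: dict[str, GenotypeCallSet]
    genetic_map: GeneticMap

    def by_group(self, group: str) -> list[GenotypeCallSet]:
        return [
            self.samples[s]
            for s in sorted(self.samples)
            if self.truth.sample_groups[s] == group
        ]

    def write(self, out_dir: str | os.PathLike) -> dict[str, str]:
        """Write per-sample VCFs, the genetic map TSV and the truth JSON."""
        out_dir = os.fspath(out_dir)
        os.makedirs(out_dir, exist_ok=True)
        paths = {}
        for name in sorted(self.samples):
            path = os.path.join(out_dir, f"{name}.vcf")
            write_vcf(
                self.samples[name].calls.values(),
                path,
                sample=name,
                contig_lengths=self.config.chromosome_lengths,
            )
            paths[name] = path
        self.genetic_map.to_tsv(os.path.join(out_dir, "genetic_map.tsv"))
        self.truth.to_json(os.path.join(out_dir, "truth.json"))
        return paths


def _alleles(pos: int) -> tuple[str, str]:
    ref = _BASES[pos % 4]
    alt = _BASES[(pos + 1 + pos // 7) % 4]
    if alt == ref:
        alt = _BASES[(pos + 2) % 4]
    return ref, alt


def _poisson_positions(
    rng: np.random.Generator, length_bp: int, density_per_mb: float
) -> np.ndarray:
    n = rng.poisson(density_per_mb * length_bp / 1e6)
    pos = np.unique(rng.integers(1, length_bp + 1, size=n))
    return pos


def simulate_congenic_cohort(
    config: SimulationConfig | None = None,
    out_dir: str | os.PathLike | None = None,
) -> CohortSimulation:
    """Simulate a congenic cohort with a known footprint.

    Returns the per-sample call sets in memory (use
    :meth:`CohortSimulation.write` or pass ``out_dir`` for VCF output) plus
    the :class:`TruthRecord`.  Identical config and seed give identical
    output, including bytes on disk.
    """
    config = config or SimulationConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)
    gmap = config.map()
    tchrom = config.target_chrom
    tlen = config.chromosome_lengths[tchrom]

    # --- breeding: N backcross meioses on the target chromosome, selecting
    # a gamete carrying the targeted allele each generation
    hap: list[Interval] = [(1, tlen)]
    for _ in range(config.n_backcrosses):
        for _attempt in range(10_000):
            g = _gamete(rng, hap, tchrom, tlen, gmap)
            if _covers(g, config.target_bp):
                hap = g
                break
        else:  # pragma: no cover - selection virtually always succeeds
            raise RuntimeError("carrier selection failed; map/target inconsistent")
    fixed_hap = hap
    fp_start, fp_end = next(
        (s, e) for s, e in fixed_hap if s <= config.target_bp <= e
    )
    extent_cm = gmap.interval_cm(tchrom, fp_start, fp_end)

    # --- unlinked residue: whole non-target donor chromosomes survive each
    # backcross with probability 1/2
    residual = [
        c
        for c in config.chromosome_lengths
        if c != tchrom
        and bool(np.all(rng.random(config.n_backcrosses) < 0.5))
    ]

    # --- samples and their donor-copy mosaics
    names_groups: list[tuple[str, str]] = (
        [(f"WT{i+1}", "WT") for i in range(config.n_wt)]
        + [(f"HET{i+1}", "HET") for i in range(config.n_het)]
        + [(f"KO{i+1}", "KO") for i in range(config.n_ko)]
    )
    mosaics: dict[str, dict[str, list[tuple[int, int, int]]]] = {}
    for name, group in names_groups:
        per_chrom: dict[str, list[tuple[int, int, int]]] = {}
        if config.intercross:
            copies_target = {"WT": 0, "HET": 1, "KO": 2}[group]
        else:
            copies_target = {"WT": 0, "HET": 1, "KO": 1}[group]
        if copies_target:
            per_chrom[tchrom] = [(s, e, copies_target) for s, e in fixed_hap]
        for c in residual:
            if config.intercross:
                copies = int(rng.choice([0, 1, 2], p=[0.25, 0.5, 0.25]))
            else:
                copies = int(rng.integers(2))
            if copies:
                per_chrom[c] = [(1, config.chromosome_lengths[c], copies)]
        mosaics[name] = per_chrom

    # --- variant layers
    variants: list[tuple[str, int, str, str, str]] = []
    donor_sites: dict[str, np.ndarray] = {}
    background_sites: dict[str, np.ndarray] = {}
    drift_sites: dict[str, dict[str, np.ndarray]] = {g: {} for _, g in names_groups}
    drift_groups = sorted({g for _, g in names_groups})
    for chrom in config.chromosome_lengths:
        length = config.chromosome_lengths[chrom]
        donor = _poisson_positions(rng, length, config.donor_density_per_mb)
        background = _poisson_positions(rng, length, config.background_density_per_mb)
        background = np.setdiff1d(background, donor)
        donor_sites[chrom] = donor
        background_sites[chrom] = background
        taken = np.union1d(donor, background)
        for group in drift_groups:
            drift = _poisson_positions(rng, length, config.drift_density_per_mb)
            drift = np.setdiff1d(drift, taken)
            taken = np.union1d(taken, drift)
            drift_sites[group][chrom] = drift
        for p in donor:
            ref, alt = _alleles(int(p))
            variants.append((chrom, int(p), ref, alt, "donor"))
        for p in background:
            ref, alt = _alleles(int(p))
            variants.append((chrom, int(p), ref, alt, "background"))
        for group in drift_groups:
            for p in drift_sites[group][chrom]:
                ref, alt = _alleles(int(p))
                variants.append((chrom, int(p), ref, alt, f"drift_{group}"))

    # --- emission
    def _copies_at(name: str, chrom: str, pos: int) -> int:
        for s, e, k in mosaics[name].get(chrom, ()):
            if s <= pos <= e:
                return k
        return 0

    samples: dict[str, GenotypeCallSet] = {}
    for name, group in names_groups:
        cs = GenotypeCallSet(name)
        for chrom in config.chromosome_lengths:
            records: list[tuple[int, Genotype]] = []
            for p in donor_sites[chrom]:
                k = _copies_at(name, chrom, int(p))
                if k == 1:
                    records.append((int(p), Genotype.HET))
                elif k == 2:
                    records.append((int(p), Genotype.HOM_ALT))
            records.extend(
                (int(p), Genotype.HOM_ALT) for p in background_sites[chrom]
            )
            records.extend(
                (int(p), Genotype.HOM_ALT) for p in drift_sites[group][chrom]
            )
            records.sort()
            for pos, geno in records:
                if config.dropout_rate and rng.random() < config.dropout_rate:
                    continue
                depth = int(rng.poisson(config.depth_mean))
                qual = float(
                    np.round(rng.gamma(config.qual_shape, config.qual_scale), 2)
                )
                ref, alt = _alleles(pos)
                key = SiteKey(chrom, pos, ref, alt)
                cs.calls[key] = VariantCall(key, geno, qual, depth, name)
        samples[name] = cs

    truth = TruthRecord(
        n_backcrosses=config.n_backcrosses,
        target_chrom=tchrom,
        target_bp=config.target_bp,
        footprint_start_bp=fp_start,
        footprint_end_bp=fp_end,
        footprint_extent_cm=extent_cm,
        fixed_haplotype=list(fixed_hap),
        residual_chromosomes=residual,
        sample_mosaics=mosaics,
        variants=variants,
        sample_groups={n: g for n, g in names_groups},
    )
    sim = CohortSimulation(config=config, truth=truth, samples=samples, genetic_map=gmap)
    if out_dir is not None:
        sim.write(out_dir)
    return sim


def donor_reference_callset(truth: TruthRecord, label: str = "donor_strain") -> GenotypeCallSet:
    """The donor strain's variant set as a call set (hom_alt everywhere),
    playing the role of a strain reference VCF for origin annotation."""
    cs = GenotypeCallSet(label)
    for key in sorted(truth.donor_variant_keys()):
        cs.calls[key] = VariantCall(key, Genotype.HOM_ALT, None, None, label)
    return cs


def default_eqtl_slopes(
    n_genes: int = 100,
    frac_nonzero: float = 0.2,
    effect: float = 4.0,
    seed: int = 0,
) -> dict[str, float]:
    """True slopes for a mixed eQTL truth: ``frac_nonzero`` of genes carry a
    slope of magnitude ``effect`` (in units of the noise SD, random sign),
    the rest are null."""
    rng = np.random.default_rng(seed)
    n_hits = int(round(frac_nonzero * n_genes))
    slopes = {}
    signs = rng.choice([-1.0, 1.0], size=n_hits)
    for i in range(n_genes):
        name = f"gene{i+1:04d}"
        slopes[name] = float(signs[i] * effect) if i < n_hits else 0.0
    return slopes


def simulate_count_table(
    slopes: Mapping[str, float],
    genotype_labels: Sequence[str],
    seed: int = 0,
    *,
    intercept: float = 100.0,
    noise_sigma: float = 1.0,
    noise: Literal["gaussian", "lognormal"] = "gaussian",
    condition: str = "control",
    sample_prefix: str = "S",
):
    """Simulate a normalized count table with expression linearly dependent
    on genotype code plus noise.

    ``expression = intercept + slope * code + eps`` with Gaussian
    ``eps ~ N(0, noise_sigma)`` or, with ``noise="lognormal"``, multiplicative
    ``exp(N(0, noise_sigma))`` noise on the linear mean (overdispersed,
    count-like).  Returns ``(CountTable, truth)`` where truth maps gene ->
    true slope.  Seed-deterministic.
    """
    import pandas as pd

    from .eqtl import CountTable, encode_genotypes

    if not slopes:
        raise ValueError("need at least one gene")
    if noise_sigma <= 0:
        raise ValueError("noise_sigma must be > 0")
    codes = np.asarray(encode_genotypes(list(genotype_labels)))
    rng = np.random.default_rng(seed)
    sample_ids = [f"{sample_prefix}{i+1}_{lab}" for i, lab in enumerate(genotype_labels)]
    rows = {}
    for gene in slopes:  # dict order: deterministic
        mean = intercept + slopes[gene] * codes
        if noise == "gaussian":
            y = mean + rng.normal(0.0, noise_sigma, size=len(codes))
        elif noise == "lognormal":
            y = mean * np.exp(rng.normal(0.0, noise_sigma, size=len(codes)))
        else:
            raise ValueError(f"unknown noise model {noise!r}")
        rows[gene] = np.maximum(y, 0.0)
    values = pd.DataFrame.from_dict(rows, orient="index", columns=sample_ids)
    table = CountTable(
        values,
        genotypes={s: lab for s, lab in zip(sample_ids, genotype_labels)},
        conditions={s: condition for s in sample_ids},
    )
    return table, dict(slopes)
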