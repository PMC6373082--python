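# Methods

`congenicscan` characterizes the genetic background of genetically
engineered mouse (GEM) lines from per-sample VCFs.  This note documents the
statistical procedures, the model behind the synthetic-data generator, the
defaults and why they were chosen, and the known limitations.

## Problem and model

Gene targeting done in 129-derived embryonic stem cells and bred onto a
C57BL/6 recipient leaves a donor-derived chromosomal segment around the
targeted locus — the *congenic footprint* — plus, at low backcross numbers,
unlinked residual donor segments and novel variants fixed by drift.  The
footprint co-segregates with the engineered allele, so knockout (KO)
samples carry donor alleles that wild-type (WT) littermates lack; that
contrast is the operational signal for every analysis in the package.

### Variant identity and filtering

A variant is identified by `(chrom, pos, ref, alt)` with one ALT per key;
multiallelic records are split on read.  Indels are matched by their exact
strings — inputs are expected left-normalized by the caller, and no
re-normalization is attempted.  Hard filters keep calls with DP > 10 and
QUAL > 30 (strict inequalities), the standard thresholds for simple diploid
calling from short-read data.  Calls lacking DP or QUAL fail the
corresponding filter; `./.` genotypes are retained on read but excluded
from all set operations.  Chromosome-name dialects (`14` vs `chr14`) are
reconciled only through an explicit mapping — never silently.

### Set operations

Replicates of one genotype are intersected on keys; the consensus genotype
follows a `strict` policy (unanimity, else flagged discordant with genotype
`missing`) or `majority` (modal, ties discordant).  Strain-reference
subtraction removes sites present in a reference VCF regardless of the
reference genotype (strain-level removal).  KO-linked dissection retains a
KO-consensus call iff its key is absent from the WT side (hom-ref and
missing WT genotypes count as absent) or present with a different genotype
state; comparison is by unphased state, so `1|1` equals `1/1`.

### Genome scan

Variants are binned in fixed windows (default 10 Mb; bin `k` covers
`[k·binsize, (k+1)·binsize)` on the 1-based coordinate).  Per chromosome,
the WT and KO binned counts form a 2×k table with ordered column scores,
tested with the Cochran-Armitage trend statistic

    T = Σᵢ tᵢ (n₁ᵢ − cᵢ R₁/N),
    Var(T) = (R₁R₂/N²) (Σᵢ tᵢ² cᵢ − (Σᵢ tᵢ cᵢ)²/N),
    z = T/√Var(T),  p = 2Φ(−|z|).

Scores default to the bin index (empty bins contribute nothing, so their
inclusion is harmless); bin-midpoint scores are available and give the same
z because the statistic is invariant under positive affine score
transformations.  Degenerate tables (an empty row, or all mass in one
column) report z = 0, p = 1 with a flag.  The per-chromosome `significant`
flag uses the raw p at α = 0.05; Bonferroni-adjusted p-values are reported
alongside.  Var(T) is the exact fixed-margin permutation variance of T up
to the finite-population factor N/(N−1); the tests verify both moments
against a permutation sample and the p/z values against an independent
implementation (R's `prop.trend.test`).

The trend test detects a *positional gradient* in the KO/WT proportion.
It is powerful for footprints near a chromosome end and weak for a broad
or centered excess that leaves the proportion flat along the chromosome —
a real limitation of this scan, visible in the simulation studies below.

### Footprint interval, cM extent, backcross number

The footprint interval is estimated from homozygous KO-linked variants
(donor alleles fixed with the targeted locus are homozygous in an
established line; `all` is available for segregating footprints).  The
default `envelope` takes min/max positions; `gap_tolerant` (the pipeline
default) keeps the largest run of occupied bins allowing one empty
internal bin, which protects the envelope from isolated stray calls
(genotyping dropout in WT creates scattered false KO-linked sites).
Physical bounds are converted to cM by linear interpolation in a
per-chromosome anchor map (TSV `chrom  bp  cM`), with terminal-slope
extrapolation outside the anchors and an optional constant-rate fallback
(default 0.5 cM/Mb, a genome-wide average for the mouse).

The backcross number uses the classical congenic expectation cM = 200/N:
each backcross meiosis truncates the retained segment on each side of the
selected locus at an Exp(100 cM) distance, so after N generations each
flank averages 100/N cM.  N is rounded to the nearest integer (both
conventions considered — nearest and ceiling — reproduce the reference
pairs 42.14 cM → 5 and 11.94 cM → 17; nearest was chosen), with a floor of
1.

### Zygosity and Mendelian cross-validation

Calls are classified homozygous (hom-alt only — a hom-ref call is never
footprint evidence), heterozygous, or other, and profiled per bin per
sample *before* any consensus so replicate-to-replicate zygosity
variability stays visible.  As a Mendelian consistency check, a
heterozygous littermate's calls are reduced to those absent from the WT
sample and heterozygous, and the fraction of KO-linked keys found in that
reduced set is reported; for a fixed homozygous footprint this coverage
approaches 1 inside the footprint.  Only variant-level coverage is
computed (gene-level coverage would require consequence annotation, which
is out of scope).

### eQTL screen

Genotypes are coded additively (WT = 1, Het = 0.5, KO = 0) and each gene's
normalized expression is regressed on the code by OLS; p is the two-sided
t-test of slope ≠ 0 with n − 2 df, selection at raw p < 0.05 by default
(Benjamini-Hochberg optional).  Candidate modifier genes are those
selected in both a control and a perturbed condition, ordered by control
p.  A perfect linear fit with nonzero slope reports the smallest positive
p with a `perfect_fit` flag; WT/KO-only designs degenerate to a two-group
comparison and are allowed.  Normalization is deliberately outside the
module: it consumes a pre-normalized table.

## The synthetic-data generator

The simulator makes the breeding scheme executable.  Meioses are modeled
as crossovers from a Poisson process on the genetic-map scale (1 per
100 cM, no interference — Haldane).  An F1 carrier heterozygous for the
donor genome is backcrossed N times to the recipient, each generation
selecting a gamete that carries the targeted allele.  The final carrier's
donor haplotype is then fixed to homozygosity by the founding intercross:
once homozygous, recombination between identical haplotypes changes
nothing, so every KO of an established line shares one footprint, the het
littermate carries it heterozygously, and WT littermates lack it.
Non-target donor chromosomes survive each backcross with probability 1/2
at whole-chromosome granularity and then segregate Mendelianly among
littermates (¼ hom / ½ het / ¼ absent after the intercross).

Emitted layers per sample: donor variants (Poisson along each chromosome,
1/Mb), shared background variants homozygous in every sample (0.1/Mb,
emulating colony variants that reference subtraction did not remove), and
drift variants private to one genotype group (0.01/Mb).  DP is Poisson
(mean 40) and QUAL Gamma(3, 100) per call, so a small realistic fraction
fails the hard filters; genotyping dropout (default 0.02) removes calls at
random.  The default cohort is 1 WT + 1 het + 3 KO samples — the embryo
design used for MEF-based characterization — on a five-chromosome
mouse-like genome (120–180 Mb) at a constant 0.5 cM/Mb, with the target at
chr5:134 Mb, a distal position matching the clearest real-world footprint
configurations.  Identical seeds give byte-identical VCFs, truth JSON and
count tables.

The count-table generator draws expression = intercept + slope·code +
noise (Gaussian, or lognormal-multiplicative for overdispersed count-like
data), with a mixed truth of 20% non-null genes at |slope|/σ = 4 by
default.

What the generator does *not* emulate: realistic mutation spectra and
indels (synthetic SNVs only), crossover interference, linkage within
non-target chromosomes (whole-chromosome residue), sequencing coverage
structure along genes (RNA-seq variant calls cluster in expressed exons),
and segregating (non-fixed) footprints.  Passing tests therefore
demonstrate the correctness of the set algebra, the scan statistics and
the estimators under this idealized genetics, not robustness to the full
noise structure of real RNA-seq calls.

## Simulation studies and their honest results

Problem sizes were chosen so the whole suite runs in seconds: 150 cohorts
(50 seeded replicates at true N ∈ {5, 10, 17}) on the five-chromosome
genome at 1 donor variant/Mb.

* **Footprint chromosome detection.**  The target chromosome ranks most
  significant in the trend scan in ≈96% of the 150 runs.  Failures are
  cohorts where breeding left a footprint of under ~2 cM (nothing to
  detect) or one so large that the KO excess covers the chromosome almost
  uniformly and has no positional gradient.

* **Backcross-number recovery.**  The gap-tolerant estimator is close to
  median-unbiased (median N̂ ≈ N), but a single line's footprint extent is
  the sum of two flank lengths, each the minimum of N Exp(100 cM) draws —
  an Erlang(2, N/100) variable with relative SD 1/√2 ≈ 71%.  Consequently
  N̂ = round(200/extent) lands within ±2 of truth in only ≈52%/27%/16% of
  lines at N = 5/10/17 even with a perfectly measured footprint; this is a
  property of recombination, not of the estimator, and the measured rates
  sit at that ceiling.  N̂ from one line should be read as an
  order-of-magnitude statement.

* **Asymptotic vs exact trend test.**  On 2×k tables with N ≤ 40 the
  normal-approximation p differs from a fixed-margin permutation p by up
  to ~0.09 — far more than Monte-Carlo error at 10⁵ permutations — because
  the permutation distribution is a lattice.  The implementation is
  validated instead by exact permutation moments, exact affine-invariance
  and row-swap antisymmetry, and agreement with R's `prop.trend.test` to
  10 significant digits.  For the genome scan's table sizes (hundreds of
  variants) the approximation error is negligible.

## Numerical and design choices

* Coordinates are 1-based inclusive everywhere; BED output converts to
  0-based half-open.
* Consensus QUAL/DP are the minima over replicates (weakest evidence).
* Bonferroni adjustment via `statsmodels`; OLS via `scipy.stats.linregress`;
  map interpolation via `numpy.interp`.
* The WT side of the dissection may be a single sample or a consensus.
* Degenerate inputs fail loudly and early: empty replicate lists, missing
  genetic map without fallback, all-one-genotype count tables, non-positive
  footprint extents.

## Limitations

* No HMM/likelihood ancestry segmentation and no multi-donor
  deconvolution; the footprint is an interval estimate from marker
  positions.
* Gene-level annotation (consequences, gene lists) is out of scope; the
  KO-linked TSV is ready for external annotators.
* The eQTL screen assumes pre-normalized, roughly homoscedastic expression
  values and an additive genotype effect.
* The trend scan's power depends on footprint position and breadth as
  described above; a nonsignificant scan does not prove the absence of
  introgression.
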