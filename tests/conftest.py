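import numpy as np
import pytest

from congenicscan import Genotype, GenotypeCallSet, SiteKey, VariantCall

VCF_HEADER = """\
##fileformat=VCFv4.2
##INFO=<ID=DP,Number=1,Type=Integer,Description="Read depth">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
##contig=<ID=chr1,length=200000000>
##contig=<ID=chr2,length=200000000>
##contig=<ID=chr14,length=125000000>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}
"""


def make_vcf(path, rows, sample="S1"):
    """Write a small single-sample VCF; rows are raw tab-joined body lines."""
    with open(path, "w") as fh:
        fh.write(VCF_HEADER.format(sample=sample))
        for row in rows:
            fh.write(row + "\n")
    return str(path)


@pytest.fixture
def vcf_factory(tmp_path):
    def factory(rows, sample="S1", name="test.vcf"):
        return make_vcf(tmp_path / name, rows, sample)

    return factory


def random_callset(rng, label="S", n=30, chroms=("chr1", "chr2"), with_quality=True):
    """A random call set for property checks."""
    cs = GenotypeCallSet(label)
    genotypes = [Genotype.HET, Genotype.HOM_ALT, Genotype.HOM_REF, Genotype.MISSING]
    for _ in range(n):
        chrom = chroms[rng.integers(len(chroms))]
        pos = int(rng.integers(1, 100_000_000))
        key = SiteKey(chrom, pos, "A", "G")
        if key in cs.calls:
            continue
        geno = genotypes[rng.choice(len(genotypes), p=[0.35, 0.45, 0.1, 0.1])]
        qual = float(rng.integers(0, 200)) if with_quality else None
        depth = int(rng.integers(0, 60)) if with_quality else None
        cs.calls[key] = VariantCall(key, geno, qual, depth, label)
    return cs
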