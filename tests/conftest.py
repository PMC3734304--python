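import numpy as np
import pytest

from cistrend import CountMatrix, GenotypeMatrix, SampleSheet, VariantMeta


@pytest.fixture
def rng():
    return np.random.default_rng(20130914)


@pytest.fixture
def small_counts():
    """2 genes x 2 samples worked normalization example."""
    return CountMatrix(["g1", "g2"], ["s1", "s2"], np.array([[2, 8], [2, 8]]))


@pytest.fixture
def trio_vcf(tmp_path):
    """A 3-sample VCF exercising GT mapping, missing calls, phasing,
    a multi-allelic record, an indel, and a region-query target at the
    SETDB2 position 50,033,188."""
    text = """\
##fileformat=VCFv4.2
##contig=<ID=13>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tA\tB\tC
13\t100\trs1\tA\tG\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1
13\t200\trs2\tC\tT\t.\tPASS\t.\tGT\t0/0\t./.\t1/1
13\t300\trs3\tG\tA\t.\tPASS\t.\tGT\t0|1\t1|1\t0|0
13\t400\trs4\tT\tA,C\t.\tPASS\t.\tGT\t0/1\t0/2\t1/2
13\t500\trs5\tTA\tT\t.\tPASS\t.\tGT\t0/0\t0/1\t0/0
13\t50033188\trs7997737\tG\tA\t.\tPASS\t.\tGT\t0/1\t0/0\t1/1
"""
    path = tmp_path / "trio.vcf"
    path.write_text(text)
    return path


@pytest.fixture
def genotypes_9():
    """9 samples x 4 variants on two chromosomes, with one missing call."""
    variants = [
        VariantMeta("v1", "13", 1_000, "A", "G"),
        VariantMeta("v2", "13", 2_000, "C", "T"),
        VariantMeta("v3", "13", 3_000, "G", "A"),
        VariantMeta("v4", "7", 2_000, "T", "C"),
    ]
    dosage = np.array(
        [
            [0, 0, 2, 1],
            [0, 1, 2, 0],
            [0, 1, 0, 1],
            [1, 0, 1, 2],
            [1, 2, 1, 0],
            [1, np.nan, 0, 1],
            [2, 0, 0, 2],
            [2, 1, 1, 0],
            [2, 2, 2, 1],
        ],
        dtype=float,
    )
    return GenotypeMatrix([f"s{i}" for i in range(9)], variants, dosage)


@pytest.fixture
def sheet_6():
    return SampleSheet(
        ["a", "b", "c", "d", "e", "f"],
        ["case", "case", "case", "control", "control", "control"],
    )
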