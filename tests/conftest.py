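import numpy as np
import pytest

from fstscan import GroupAssignment, VariantTable


def make_table(positions, genotypes, chrom="chr1", qual=100.0, info=None,
               samples=None):
    """Build a small VariantTable from positions and a dosage matrix."""
    pos = np.asarray(positions, dtype=np.int64)
    geno = np.asarray(genotypes, dtype=np.int8)
    if geno.ndim == 1:
        geno = geno.reshape(len(pos), -1)
    n, s = geno.shape
    if samples is None:
        samples = [f"s{i}" for i in range(s)]
    chroms = (
        np.asarray(chrom, dtype=object)
        if not np.isscalar(chrom)
        else np.full(n, chrom, dtype=object)
    )
    quals = (
        np.full(n, qual, dtype=float)
        if np.isscalar(qual)
        else np.asarray(qual, dtype=float)
    )
    full_info = {
        k: np.full(n, np.nan) for k in ("QD", "FS", "MQ", "MQRankSum", "ReadPosRankSum")
    }
    if info:
        for k, v in info.items():
            full_info[k] = np.asarray(v, dtype=float)
    return VariantTable(
        chrom=chroms,
        pos=pos,
        ref=np.full(n, "A", dtype=object),
        alt=np.full(n, "G", dtype=object),
        qual=quals,
        info=full_info,
        genotypes=geno,
        samples=samples,
    )


def two_group_assignment(n1, n2, samples=None):
    if samples is None:
        samples = [f"s{i}" for i in range(n1 + n2)]
    return GroupAssignment(
        {s: ("g1" if i < n1 else "g2") for i, s in enumerate(samples)}
    )


@pytest.fixture
def toy_vcf(tmp_path):
    """Three-record VCF: two biallelic SNPs and one indel."""
    text = """##fileformat=VCFv4.2
##INFO=<ID=QD,Number=1,Type=Float,Description="x">
##INFO=<ID=FS,Number=1,Type=Float,Description="x">
##INFO=<ID=MQ,Number=1,Type=Float,Description="x">
##INFO=<ID=MQRankSum,Number=1,Type=Float,Description="x">
##INFO=<ID=ReadPosRankSum,Number=1,Type=Float,Description="x">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tsampleA\tsampleB\tsampleC
chr1\t100\t.\tA\tG\t50\t.\tQD=10;MQ=50\tGT\t0|1\t1/1\t./.
chr1\t200\t.\tAT\tA\t60\t.\tQD=12\tGT\t0/0\t0/1\t0/0
chr1\t300\t.\tC\tT\t70\t.\tQD=20;FS=5\tGT\t0/0\t0/0\t1/1
"""
    path = tmp_path / "toy.vcf"
    path.write_text(text)
    return path
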