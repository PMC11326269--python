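import pandas as pd
import pytest

from linkedhap.simulate import scenario

TOY_VCF = """\
##fileformat=VCFv4.2
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=PS,Number=1,Type=Integer,Description="Phase set">
##contig=<ID=chr1>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1
chr1\t100\t.\tA\tG\t.\tPASS\t.\tGT:PS\t0|1:100
chr1\t250\t.\tC\tT\t.\tPASS\t.\tGT:PS\t1|0:100
chr1\t5000\t.\tG\tA\t.\tPASS\t.\tGT:PS\t0|1:5000
chr1\t7000\t.\tT\tC\t.\tPASS\t.\tGT\t0/1
"""

EMPTY_VCF = """\
##fileformat=VCFv4.2
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##contig=<ID=chr1>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1
"""


@pytest.fixture
def toy_vcf(tmp_path):
    """Three phased het variants in phase sets {100, 100, 5000} plus one unphased."""
    path = tmp_path / "toy.vcf"
    path.write_text(TOY_VCF)
    return path


@pytest.fixture
def empty_vcf(tmp_path):
    path = tmp_path / "empty.vcf"
    path.write_text(EMPTY_VCF)
    return path


@pytest.fixture(scope="session")
def nras_bundle():
    return scenario("nras_like", 0)


@pytest.fixture(scope="session")
def actg_bundle():
    return scenario("actg1_like", 0)


def make_obs(rows):
    """Observation table from (barcode, chrom, pos, allele, hap[, phase_set]) tuples."""
    full = [(r + (-1,))[:6] for r in rows]
    return pd.DataFrame(
        full, columns=["barcode", "chrom", "pos", "allele", "hap", "phase_set"]
    )
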