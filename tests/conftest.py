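import numpy as np
import pytest

from phaseai.vcf_io import MarkerTable

VCF_HEADER = """\
##fileformat=VCFv4.2
##contig=<ID=1,length=100000000>
##contig=<ID=2,length=100000000>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{samples}
"""

PHASED_HEADER = """\
##fileformat=VCFv4.2
##contig=<ID=1,length=100000000>
##contig=<ID=2,length=100000000>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{samples}
"""


def write_vcf(path, rows, samples=("S1",), phased=False):
    """rows: (chrom, pos, ref, alt, [per-sample fields...]).

    Per-sample field is 'GT' for phased files or 'GT:AD' otherwise,
    e.g. '0/1:40,40' or '0|1'.
    """
    header = PHASED_HEADER if phased else VCF_HEADER
    fmt = "GT" if phased else "GT:AD"
    with open(path, "w") as fh:
        fh.write(header.format(samples="\t".join(samples)))
        for row in rows:
            chrom, pos, ref, alt = row[:4]
            fields = "\t".join(row[4:])
            fh.write(f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t.\t{fmt}\t{fields}\n")
    return path


@pytest.fixture
def make_sample_vcf(tmp_path):
    def _make(rows, name="sample.vcf", samples=("S1",)):
        return write_vcf(tmp_path / name, rows, samples=samples, phased=False)

    return _make


@pytest.fixture
def make_phased_vcf(tmp_path):
    def _make(rows, name="phased.vcf", samples=("S1",)):
        return write_vcf(tmp_path / name, rows, samples=samples, phased=True)

    return _make


def make_table(n=10, chrom="1", seed=0, start=1000, spacing=1000):
    """A small balanced MarkerTable with deterministic content."""
    rng = np.random.default_rng(seed)
    pos = start + spacing * np.arange(n)
    ref = rng.integers(30, 50, size=n)
    alt = rng.integers(30, 50, size=n)
    hap1 = rng.integers(0, 2, size=n)
    return MarkerTable(
        np.full(n, chrom, dtype=object), pos, ref, alt, hap1, 1 - hap1
    )
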