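import numpy as np
import pytest
from hypothesis import settings

from metareid import ErrorModel, SiteKey, SitePanel

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
    '##INFO=<ID=AF,Number=A,Type=Float,Description="Allele frequency">\n'
)


def write_vcf(path, records, samples=()):
    """Write a minimal VCF; records are (chrom, pos, ref, alt, info, gts)."""
    cols = "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO"
    if samples:
        cols += "\tFORMAT\t" + "\t".join(samples)
    with open(path, "w") as fh:
        fh.write(VCF_HEADER)
        fh.write(cols + "\n")
        for chrom, pos, ref, alt, info, gts in records:
            line = f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\t.\t{info or '.'}"
            if samples:
                line += "\tGT\t" + "\t".join(gts)
            fh.write(line + "\n")
    return path


@pytest.fixture
def em():
    return ErrorModel()


@pytest.fixture
def small_panel():
    """Four-site panel on one chromosome with a single population."""
    sites = [
        SiteKey("1", 100, "A", "G"),
        SiteKey("1", 200, "C", "T"),
        SiteKey("1", 300, "G", "A"),
        SiteKey("1", 400, "T", "C"),
    ]
    return SitePanel(sites=sites, freq={"POP": np.array([0.1, 0.3, 0.5, 0.7])})
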