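import textwrap

import pytest

from mirvar.intervals import GenomicInterval
from mirvar.mirna_geometry import MirnaGene
from mirvar.variant_model import Variant


def write_vcf(path, body_lines, samples=("S1", "S2", "S3")):
    """Write a minimal single-contig VCF with GT-only FORMAT."""
    header = textwrap.dedent(
        """\
        ##fileformat=VCFv4.2
        ##contig=<ID=chr1,length=100000>
        ##contig=<ID=chr2,length=100000>
        ##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
        """
    )
    cols = "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples)
    path.write_text(header + cols + "\n" + "".join(l + "\n" for l in body_lines))
    return path


def snp(chrom, pos, ref="G", alt="A", af=0.5, af_by_breed=None):
    """Shorthand for a frequency-annotated SNP used in geometry tests."""
    return Variant(
        interval=GenomicInterval(chrom, pos, pos + len(ref) - 1),
        ref=ref,
        alt=alt,
        change="SNP" if len(ref) == len(alt) == 1 else "deletion",
        indel_length=abs(len(ref) - len(alt)),
        af_overall=af,
        af_by_breed=af_by_breed or {"Holstein": af},
        n_called=10,
    )


@pytest.fixture
def plus_gene():
    """One + strand gene: precursor [1000,1080], arm [1010,1031], seed [1011,1016]."""
    return MirnaGene(
        name="syn-miR-plus",
        precursor=GenomicInterval("chr1", 1000, 1080, "+"),
        mature_arms=(("syn-miR-plus-5p", GenomicInterval("chr1", 1010, 1031, "+")),),
    )


@pytest.fixture
def minus_gene():
    """One - strand gene: precursor [2000,2080], arm [2040,2061], seed [2055,2060]."""
    return MirnaGene(
        name="syn-miR-minus",
        precursor=GenomicInterval("chr1", 2000, 2080, "-"),
        mature_arms=(("syn-miR-minus-3p", GenomicInterval("chr1", 2040, 2061, "-")),),
    )
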