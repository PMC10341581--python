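"""Shared fixtures: small hand-written VCF/GFF3/DEG inputs built at test time."""

from __future__ import annotations

import textwrap

import pytest

# Hand-constructed two-bulk VCF: a plain biallelic SNP, a multiallelic SNP,
# an indel (must be skipped), a symbolic allele (skipped) and a record
# without AD (skipped).
VCF_TEXT = textwrap.dedent(
    """\
    ##fileformat=VCFv4.2
    ##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
    ##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">
    ##contig=<ID=chr6,length=174000000>
    ##contig=<ID=chr9,length=160000000>
    #CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tmut_bulk\twt_bulk
    chr6\t500\t.\tG\tT\t50\tPASS\t.\tGT:AD\t1/1:1,19\t0/1:10,12
    chr9\t100\t.\tA\tC\t50\tPASS\t.\tGT:AD\t1/1:0,12\t0/1:8,4
    chr9\t200\t.\tA\tC,T\t50\tPASS\t.\tGT:AD\t1/2:2,3,5\t0/1:6,1,1
    chr9\t300\t.\tA\tAT\t50\tPASS\t.\tGT:AD\t0/1:5,5\t0/1:5,5
    chr9\t400\t.\tA\t<DEL>\t50\tPASS\t.\tGT:AD\t0/1:5,5\t0/1:5,5
    chr9\t500\t.\tC\tG\t50\tPASS\t.\tGT\t0/1\t0/1
    """
)

GFF3_TEXT = textwrap.dedent(
    """\
    ##gff-version 3
    chr6\ttest\tgene\t8000000\t8004000\t.\t+\t.\tID=gene:GX;biotype=protein_coding
    chr6\ttest\tmRNA\t8000000\t8004000\t.\t+\t.\tID=tx:GX_T001;Parent=gene:GX
    chr6\ttest\texon\t8000000\t8001000\t.\t+\t.\tParent=tx:GX_T001
    chr9\ttest\tgene\t95000000\t95003000\t.\t-\t.\tID=GY
    chr9\ttest\tgene\t121000000\t121005000\t.\t+\t.\tID=GZ
    """
)

DEG_TEXT = textwrap.dedent(
    """\
    gene_id\tlog2fc\tpadj
    gA\t1.3\t0.01
    gB\t-0.8\t0.04
    gC\t2.2\t0.001
    """
)


@pytest.fixture
def vcf_path(tmp_path):
    p = tmp_path / "bulks.vcf"
    p.write_text(VCF_TEXT)
    return p


@pytest.fixture
def gff3_path(tmp_path):
    p = tmp_path / "genes.gff3"
    p.write_text(GFF3_TEXT)
    return p


@pytest.fixture
def deg_path(tmp_path):
    p = tmp_path / "deg_III.tsv"
    p.write_text(DEG_TEXT)
    return p
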